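"""Generate a balanced synthetic cytology dataset and inspect its structure.

Renders stage-labeled smears (leukocyte/cornified/nucleated mixtures per
stage), writes a manifest CSV, and shows that the curation filters keep
everything the generator produces.
"""

from estrocycle import apply_exclusion_filters, generate_dataset, write_manifest

manifest = generate_dataset(10, out_dir="scratch/example_ds", seed=0)
write_manifest(manifest, "scratch/example_ds/manifest.csv")

print(f"{len(manifest)} images, per-stage counts: {manifest.stage_counts()}")
rec = manifest[0]
print(f"first record: {rec.benchmark_stage}, stain {rec.stain}, "
      f"{rec.total_cells} cells, leukocyte fraction "
      f"{rec.cell_proportions.leukocyte_frac:.2f}")

kept, log = apply_exclusion_filters(manifest)
print(f"exclusion filters removed {len(log)} of {len(manifest)} records")
# Expected: 40 balanced records; the first (diestrus) record is
# leukocyte-dominant; no record trips the <300 px / <10 cells filters.
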