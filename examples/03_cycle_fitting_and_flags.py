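"""Fit the archetypal cycle to a noisy multi-day sequence and raise flags.

Simulates 12 daily samples at a hidden phase with 10% label noise,
recovers the phase by Pearson-correlation grid search, then shows the
pseudopregnancy detector on a sequence with an induced anestrous episode.
"""

import numpy as np

from estrocycle import (
    SequenceSpec,
    detect_anestrus_from_counts,
    detect_pseudopregnancy,
    fit_cycle_phase,
    generate_cycle_sequence,
    simulate_stage_sequence,
)

times, true_stages, labels = simulate_stage_sequence(
    SequenceSpec(n_days=12, true_phase=0.4, label_noise=0.1, seed=3)
)
fit = fit_cycle_phase(times, labels)
print(f"true phase 0.4 -> fitted {fit.best_phase:.1f} (r={fit.pearson_r:.3f})")
print(f"outlier samples: {fit.outlier_indices}")

# a sequence that enters pseudopregnancy on day 8
spec = SequenceSpec(n_days=16, pseudopregnancy_onset_day=8, seed=4)
manifest, _ = generate_cycle_sequence(spec)
stages = [r.benchmark_stage for r in manifest]
t = np.array([r.collected_at for r in manifest])
pp = detect_pseudopregnancy(t, stages)
print(f"pseudopregnancy: {pp.status} at sample {pp.onset_index} "
      f"(baseline diestrus run {pp.baseline_days} days)")

an = detect_anestrus_from_counts(t, [r.cell_proportions for r in manifest])
print(f"anestrus flag from cell counts: {an.flag}")
# The fitted phase lands within one 0.1-cycle grid step of the truth;
# the prolonged diestrus run after day 8 trips the 1.5x rule and the
# >90%-leukocyte run trips the anestrus rule.
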