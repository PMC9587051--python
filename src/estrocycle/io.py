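"""Dataset manifests: CSV reading/writing, metadata records, exclusion filters.

A dataset is described by a manifest CSV with one row per cytology image.
Recognized columns::

    image_path, subject_id, species, strain, stain, magnification, lab,
    collected_at_days, stage, leukocyte_frac, cornified_frac,
    nucleated_frac, total_cells, exclude, width, height

Only ``image_path`` is required.  ``stage`` accepts canonical names,
single-letter aliases (D/P/E/M) and transition labels ("proestrus/estrus").
``collected_at_days`` is real-valued days since the subject's first sample.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .results import ClassificationResult
from .stages import normalize_stage

logger = logging.getLogger("estrocycle")

KNOWN_STAINS = ("HE", "Shorr", "Giemsa", "CresylViolet", "CrystalViolet")
KNOWN_SPECIES = ("mouse", "rat")
KNOWN_MAGNIFICATIONS = ("10x", "20x")

_STAIN_ALIASES = {
    "he": "HE",
    "h&e": "HE",
    "hematoxylin and eosin": "HE",
    "shorr": "Shorr",
    "sh": "Shorr",
    "giemsa": "Giemsa",
    "ge": "Giemsa",
    "cresylviolet": "CresylViolet",
    "cresyl violet": "CresylViolet",
    "cresyl_violet": "CresylViolet",
    "crev": "CresylViolet",
    "crystalviolet": "CrystalViolet",
    "crystal violet": "CrystalViolet",
    "crystal_violet": "CrystalViolet",
    "cryv": "CrystalViolet",
}


class ManifestSchemaError(ValueError):
    """Raised when a manifest CSV is missing a required column."""


class ManifestRowError(ValueError):
    """Raised when a manifest data row cannot be parsed (carries line number)."""


@dataclass(frozen=True)
class CellCounts:
    """Proportions of the three diagnostic cell classes (sum to 1)."""

    leukocyte_frac: float
    cornified_frac: float
    nucleated_frac: float

    def __post_init__(self) -> None:
        for v in (self.leukocyte_frac, self.cornified_frac, self.nucleated_frac):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError("cell fractions must lie in [0, 1]")
        total = self.leukocyte_frac + self.cornified_frac + self.nucleated_frac
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"cell fractions must sum to 1 (got {total:.8f})")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.leukocyte_frac, self.cornified_frac, self.nucleated_frac]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "CellCounts":
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class ImageRecord:
    """One cytology image plus its acquisition metadata.

    ``benchmark_stage`` is the expert consensus label when available;
    ``cell_proportions``/``total_cells`` carry manual counts when the source
    lab recorded them.
    """

    image_path: str
    subject_id: str = ""
    species: str = "other"
    strain: str = ""
    stain: str = "other"
    magnification: str = "other"
    lab: str = ""
    collected_at: float | None = None
    benchmark_stage: str | None = None
    cell_proportions: CellCounts | None = None
    total_cells: int | None = None
    exclude: bool = False
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        if self.benchmark_stage is not None:
            self.benchmark_stage = normalize_stage(self.benchmark_stage)
        for dim in (self.width, self.height):
            if dim is not None and dim < 1:
                raise ValueError("image dimensions must be >= 1 pixel")

    def replace(self, **kw) -> "ImageRecord":
        return replace(self, **kw)


@dataclass
class DatasetManifest:
    """An ordered collection of image records with a provenance note."""

    records: list[ImageRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("image_path values in a manifest must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ImageRecord:
        return self.records[i]

    def stage_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            if r.benchmark_stage is not None:
                counts[r.benchmark_stage] = counts.get(r.benchmark_stage, 0) + 1
        return counts

    def subset(self, indices: Iterable[int], provenance: str | None = None) -> "DatasetManifest":
        return DatasetManifest(
            records=[self.records[i] for i in indices],
            provenance=provenance if provenance is not None else self.provenance,
        )


MANIFEST_COLUMNS = (
    "image_path",
    "subject_id",
    "species",
    "strain",
    "stain",
    "magnification",
    "lab",
    "collected_at_days",
    "stage",
    "leukocyte_frac",
    "cornified_frac",
    "nucleated_frac",
    "total_cells",
    "exclude",
    "width",
    "height",
)


def _norm_stain(value: str) -> str:
    s = str(value).strip()
    if s in KNOWN_STAINS:
        return s
    if s.lower() in _STAIN_ALIASES:
        return _STAIN_ALIASES[s.lower()]
    if s and s.lower() not in ("", "other", "nan"):
        logger.warning("unknown stain %r mapped to 'other'", value)
    return "other"


def _norm_species(value: str) -> str:
    s = str(value).strip().lower()
    if s in KNOWN_SPECIES:
        return s
    if s and s not in ("", "other", "nan"):
        logger.warning("unknown species %r mapped to 'other'", value)
    return "other"


def _norm_magnification(value: str) -> str:
    s = str(value).strip().lower()
    if s in KNOWN_MAGNIFICATIONS:
        return s
    if s and s not in ("", "other", "nan"):
        logger.warning("unknown magnification %r mapped to 'other'", value)
    return "other"


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n", ""):
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def _parse_row(row: pd.Series) -> ImageRecord:
    def get(col, default=None):
        v = row.get(col, default)
        return default if _is_missing(v) else v

    props = None
    fracs = [get(c) for c in ("leukocyte_frac", "cornified_frac", "nucleated_frac")]
    if all(v is not None for v in fracs):
        props = CellCounts(*(float(v) for v in fracs))
    total = get("total_cells")
    stage = get("stage")
    width, height = get("width"), get("height")
    return ImageRecord(
        image_path=str(row["image_path"]),
        subject_id=str(get("subject_id", "") or ""),
        species=_norm_species(get("species", "") or ""),
        strain=str(get("strain", "") or ""),
        stain=_norm_stain(get("stain", "") or ""),
        magnification=_norm_magnification(get("magnification", "") or ""),
        lab=str(get("lab", "") or ""),
        collected_at=None if get("collected_at_days") is None else float(row["collected_at_days"]),
        benchmark_stage=None if stage is None else normalize_stage(stage),
        cell_proportions=props,
        total_cells=None if total is None else int(total),
        exclude=_parse_bool(get("exclude", False)),
        width=None if width is None else int(width),
        height=None if height is None else int(height),
    )


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest CSV into a :class:`DatasetManifest`.

    Raises :class:`ManifestSchemaError` when ``image_path`` is missing and
    :class:`ManifestRowError` (with the 1-based CSV line number) when a data
    row cannot be parsed.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "image_path" not in df.columns:
        raise ManifestSchemaError("manifest is missing required column 'image_path'")
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            # +2: header line plus 1-based indexing
            raise ManifestRowError(f"line {i + 2}: {exc}") from exc
    return DatasetManifest(records=records, provenance=str(path))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Write a manifest to CSV; ``load_manifest`` round-trips it exactly."""
    rows = []
    for r in manifest.records:
        p = r.cell_proportions
        rows.append(
            {
                "image_path": r.image_path,
                "subject_id": r.subject_id,
                "species": r.species,
                "strain": r.strain,
                "stain": r.stain,
                "magnification": r.magnification,
                "lab": r.lab,
                "collected_at_days": r.collected_at,
                "stage": r.benchmark_stage,
                "leukocyte_frac": None if p is None else p.leukocyte_frac,
                "cornified_frac": None if p is None else p.cornified_frac,
                "nucleated_frac": None if p is None else p.nucleated_frac,
                "total_cells": r.total_cells,
                "exclude": r.exclude,
                "width": r.width,
                "height": r.height,
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


@dataclass
class ExclusionLogEntry:
    image_path: str
    reason: str


def apply_exclusion_filters(
    manifest: DatasetManifest,
    min_pixels: int = 300,
    min_cells: int = 10,
) -> tuple[DatasetManifest, list[ExclusionLogEntry]]:
    """Apply the standard curation filters and return (kept, exclusion log).

    Records are dropped when their smaller image dimension is below
    ``min_pixels``, when an accompanying manual cell count is below
    ``min_cells``, or when the manual ``exclude`` flag is set.  Records
    without dimensions or counts are retained (missing data is not grounds
    for exclusion).  The operation is idempotent.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    kept, log = [], []
    for r in manifest.records:
        if r.exclude:
            log.append(ExclusionLogEntry(r.image_path, "manual exclude flag"))
        elif (
            r.width is not None
            and r.height is not None
            and min(r.width, r.height) < min_pixels
        ):
            log.append(
                ExclusionLogEntry(
                    r.image_path,
                    f"min dimension {min(r.width, r.height)} < {min_pixels} pixels",
                )
            )
        elif r.total_cells is not None and r.total_cells < min_cells:
            log.append(
                ExclusionLogEntry(r.image_path, f"{r.total_cells} < {min_cells} cells")
            )
        else:
            kept.append(r)
    for entry in log:
        logger.info("excluded %s: %s", entry.image_path, entry.reason)
    return DatasetManifest(records=kept, provenance=manifest.provenance), log


def write_results(results: Sequence[ClassificationResult], path: str | Path) -> Path:
    """Serialize classification results to schema-stable JSON."""
    if len(results) == 0:
        raise ValueError("results collection must be non-empty")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [r.to_dict() for r in results]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_results(path: str | Path) -> list[ClassificationResult]:
    payload = json.loads(Path(path).read_text())
    return [ClassificationResult.from_dict(d) for d in payload]
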