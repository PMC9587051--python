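"""Seeded generator of stage-labeled synthetic cytology images and sequences.

The generator emulates the statistical structure that makes the four estrous
stages distinguishable in real smears — the relative proportions and sizes of
leukocytes (small dark discs), nucleated epithelial cells (medium discs with a
darker nucleus) and cornified epithelial cells (large irregular anucleated
polygons, optionally clumped) — without attempting photorealism.  Cells are
placed without overlap so that rendered images carry exact, recoverable
ground-truth counts; every draw is reproducible from a seed.

Stage mixtures follow the qualitative ordering seen in real cytology:
diestrus leukocyte-dominant, proestrus nucleated-dominant, estrus
cornified-dominant with clumping, metestrus mixed with leukocytes present.
The default mixture means are package choices, not measured values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .io import CellCounts, DatasetManifest, ImageRecord
from .stages import CANONICAL_STAGES, flanking_stages, is_transition, normalize_stage
from .posthoc import ArchetypalCycle, default_cycle

logger = logging.getLogger("estrocycle")

CELL_TYPES = ("leukocyte", "cornified", "nucleated")


@dataclass
class CellRenderParams:
    """Geometry, intensity and noise parameters of the renderer.

    Radii are in pixels at the native render size and must respect the
    biological size ordering leukocyte < nucleated < cornified.  Intensities
    are gray levels in [0, 1] on a light background, mimicking brightfield
    stains where cells absorb light.
    """

    image_size: int = 448
    background_level: float = 0.92
    leukocyte_radius: tuple[float, float] = (2.0, 4.0)
    nucleated_radius: tuple[float, float] = (6.0, 9.0)
    cornified_radius: tuple[float, float] = (12.0, 16.0)
    # disjoint intensity bands per cell type: cell identity is recoverable
    # from a noise-free render by thresholding alone
    leukocyte_intensity: tuple[float, float] = (0.25, 0.40)
    nucleated_intensity: tuple[float, float] = (0.50, 0.62)
    nucleus_intensity: tuple[float, float] = (0.05, 0.15)
    cornified_intensity: tuple[float, float] = (0.68, 0.82)
    nucleus_scale: float = 0.45
    clumping_strength: float = 0.7
    clump_sd: float = 28.0
    noise_sd: float = 0.01
    stain_tints: dict = field(
        default_factory=lambda: {
            "HE": (0.90, 0.62, 0.78),
            "Shorr": (0.92, 0.68, 0.58),
            "Giemsa": (0.62, 0.68, 0.92),
            "CresylViolet": (0.74, 0.62, 0.88),
            "CrystalViolet": (0.66, 0.56, 0.84),
            "other": (0.78, 0.78, 0.78),
        }
    )

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 pixels")
        if not (
            self.leukocyte_radius[1] < self.nucleated_radius[0] < self.nucleated_radius[1] < self.cornified_radius[0]
        ):
            raise ValueError("size ranges must be ordered leukocyte < nucleated < cornified")
        for rng_ in (
            self.leukocyte_intensity,
            self.nucleated_intensity,
            self.nucleus_intensity,
            self.cornified_intensity,
        ):
            if not (0 <= rng_[0] <= rng_[1] <= 1):
                raise ValueError("intensity ranges must lie in [0, 1]")
        if not 0 <= self.clumping_strength <= 1:
            raise ValueError("clumping_strength must lie in [0, 1]")

    def radius_range(self, cell_type: str) -> tuple[float, float]:
        return {
            "leukocyte": self.leukocyte_radius,
            "nucleated": self.nucleated_radius,
            "cornified": self.cornified_radius,
        }[cell_type]


@dataclass
class StageMixture:
    """Per-stage cell-type composition: Dirichlet means, spread, and totals.

    ``means`` maps each canonical stage to (leukocyte, cornified, nucleated)
    proportions; draws come from a Dirichlet with parameters
    ``concentration * mean`` (``concentration=inf`` collapses to the mean).
    """

    means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "diestrus": (0.85, 0.05, 0.10),
            "proestrus": (0.10, 0.10, 0.80),
            "estrus": (0.05, 0.90, 0.05),
            "metestrus": (0.40, 0.30, 0.30),
        }
    )
    concentration: float = 80.0
    total_cells: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "diestrus": (120, 240),
            "proestrus": (80, 160),
            "estrus": (50, 90),
            "metestrus": (80, 160),
        }
    )
    pseudopregnant_mean: tuple[float, float, float] = (0.95, 0.02, 0.03)

    def __post_init__(self) -> None:
        for stage, mean in self.means.items():
            if abs(sum(mean) - 1.0) > 1e-9:
                raise ValueError(f"mixture mean for {stage} must sum to 1")

    def mean_for(self, stage: str) -> np.ndarray:
        """Mean proportions for a stage; transitions average their flanks."""
        s = normalize_stage(stage)
        if is_transition(s):
            a, b = flanking_stages(s)
            return (np.asarray(self.means[a]) + np.asarray(self.means[b])) / 2.0
        return np.asarray(self.means[s], dtype=float)

    def total_range_for(self, stage: str) -> tuple[int, int]:
        s = normalize_stage(stage)
        if is_transition(s):
            a, b = flanking_stages(s)
            lo = (self.total_cells[a][0] + self.total_cells[b][0]) // 2
            hi = (self.total_cells[a][1] + self.total_cells[b][1]) // 2
            return lo, hi
        return self.total_cells[s]


@dataclass
class SequenceSpec:
    """Specification of a multi-day sampling sequence."""

    n_days: int
    samples_per_day: int = 1
    true_phase: float = 0.0
    label_noise: float = 0.0
    pseudopregnancy_onset_day: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.samples_per_day < 1:
            raise ValueError("samples_per_day must be >= 1")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must lie in [0, 1]")
        if not 0 <= self.true_phase < 1:
            raise ValueError("true_phase must lie in [0, 1)")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_stage_proportions(
    stage: str,
    mix: StageMixture | None = None,
    seed: int | np.random.Generator = 0,
    min_leukocyte: float | None = None,
) -> tuple[CellCounts, int]:
    """Draw a (cell proportions, total cell count) pair for one sample.

    ``min_leukocyte`` rejects draws below a leukocyte floor (used for
    pseudopregnant/anestrous samples, which show >90% leukocytes).
    """
    mix = mix or StageMixture()
    rng = _as_rng(seed)
    mean = mix.mean_for(stage)
    if math.isinf(mix.concentration):
        p = mean.copy()
    else:
        alpha = np.maximum(mean * mix.concentration, 1e-3)
        p = rng.dirichlet(alpha)
        if min_leukocyte is not None:
            for _ in range(200):
                if p[0] >= min_leukocyte:
                    break
                p = rng.dirichlet(alpha)
            else:
                p = mean.copy()
    lo, hi = mix.total_range_for(stage)
    total = int(rng.integers(lo, hi + 1))
    return CellCounts.from_array(p), total


def _place_cells(
    rng: np.random.Generator,
    n: int,
    r_range: tuple[float, float],
    placed_xy: list,
    placed_r: list,
    size: int,
    clump_centers: np.ndarray | None = None,
    clump_strength: float = 0.0,
    clump_sd: float = 28.0,
    max_tries: int = 400,
) -> list[tuple[float, float, float]]:
    """Dart-throw ``n`` non-overlapping cells; returns (row, col, radius)."""
    out = []
    for _ in range(n):
        r = rng.uniform(*r_range)
        lo, hi = r + 1.0, size - r - 2.0
        pos = None
        for _try in range(max_tries):
            if clump_centers is not None and len(clump_centers) and rng.random() < clump_strength:
                c = clump_centers[rng.integers(len(clump_centers))]
                cand = c + rng.normal(0.0, clump_sd, size=2)
                cand = np.clip(cand, lo, hi)
            else:
                cand = rng.uniform(lo, hi, size=2)
            if placed_xy:
                d2 = np.sum((np.asarray(placed_xy) - cand) ** 2, axis=1)
                min_sep = (np.asarray(placed_r) + r + 2.0) ** 2
                if np.any(d2 < min_sep):
                    continue
            pos = cand
            break
        if pos is None:  # dense packing fallback; essentially unreachable at defaults
            logger.warning("cell placement fell back to overlapping position")
            pos = rng.uniform(lo, hi, size=2)
        placed_xy.append(pos)
        placed_r.append(r)
        out.append((float(pos[0]), float(pos[1]), float(r)))
    return out


def render_cytology_image(
    stage: str,
    params: CellRenderParams | None = None,
    mix: StageMixture | None = None,
    seed: int | np.random.Generator = 0,
    stain: str = "other",
    out_path: str | Path | None = None,
    min_leukocyte: float | None = None,
):
    """Render one synthetic smear; returns (rgb image, counts, fractions, total).

    The returned integer ``counts`` are exactly the numbers of cells drawn:
    placement is overlap-free and fully inside the frame, so a connected-
    component counter on the noise-free image recovers them exactly.
    """
    params = params or CellRenderParams()
    mix = mix or StageMixture()
    rng = _as_rng(seed)
    fractions, total = sample_stage_proportions(stage, mix, rng, min_leukocyte=min_leukocyte)
    if total <= 0:
        raise ValueError("total cell count must be positive")
    counts_arr = rng.multinomial(total, fractions.as_array())
    counts = dict(zip(CELL_TYPES, (int(c) for c in counts_arr)))
    realized = CellCounts.from_array(counts_arr / total)

    size = params.image_size
    img = np.full((size, size), params.background_level, dtype=np.float64)
    placed_xy: list = []
    placed_r: list = []

    # cornified first: clump centers attract them when clumping is on
    n_corn = counts["cornified"]
    centers = None
    if n_corn > 0 and params.clumping_strength > 0:
        n_centers = max(1, n_corn // 6)
        centers = rng.uniform(40, size - 40, size=(n_centers, 2))
    for row, col, r in _place_cells(
        rng, n_corn, params.cornified_radius, placed_xy, placed_r, size,
        clump_centers=centers, clump_strength=params.clumping_strength,
        clump_sd=params.clump_sd,
    ):
        # jittered regular angles: irregular outline without sliver pinches
        n_vert = int(rng.integers(8, 13))
        step = 2 * np.pi / n_vert
        angles = (
            np.arange(n_vert) * step
            + rng.uniform(0, 2 * np.pi)
            + rng.uniform(-0.3, 0.3, n_vert) * step
        )
        radii = rng.uniform(0.8, 1.0, n_vert) * r
        rr, cc = draw_polygon(row + radii * np.sin(angles), col + radii * np.cos(angles), img.shape)
        img[rr, cc] = rng.uniform(*params.cornified_intensity)

    for row, col, r in _place_cells(
        rng, counts["nucleated"], params.nucleated_radius, placed_xy, placed_r, size
    ):
        rr, cc = draw_disk((row, col), r, shape=img.shape)
        img[rr, cc] = rng.uniform(*params.nucleated_intensity)
        rr, cc = draw_disk((row, col), max(1.5, params.nucleus_scale * r), shape=img.shape)
        img[rr, cc] = rng.uniform(*params.nucleus_intensity)

    for row, col, r in _place_cells(
        rng, counts["leukocyte"], params.leukocyte_radius, placed_xy, placed_r, size
    ):
        rr, cc = draw_disk((row, col), r, shape=img.shape)
        img[rr, cc] = rng.uniform(*params.leukocyte_intensity)

    tint = np.asarray(params.stain_tints.get(stain, params.stain_tints["other"]))
    rgb = img[:, :, None] * tint[None, None, :]
    if params.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out_path, (rgb * 255).round().astype(np.uint8))
    return rgb, counts, realized, total


def generate_dataset(
    n_per_stage: int,
    out_dir: str | Path | None = None,
    params: CellRenderParams | None = None,
    mix: StageMixture | None = None,
    stains: Sequence[str] = ("HE", "Shorr"),
    seed: int = 0,
    n_subjects: int = 12,
    render: bool = True,
) -> DatasetManifest:
    """Generate a balanced labeled dataset of ``4 * n_per_stage`` records.

    Stains cycle deterministically over the global record index; subjects
    cycle over a pool of ``n_subjects`` synthetic animals (first half mice,
    second half rats).  With ``render=False`` only metadata records are
    produced (no PNGs written) — useful for exercising splitting and
    filtering at scale.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    params = params or CellRenderParams()
    mix = mix or StageMixture()
    out_dir = Path(out_dir) if out_dir is not None else None
    if render and out_dir is None:
        raise ValueError("out_dir is required when render=True")
    root = np.random.default_rng(seed)
    records = []
    idx = 0
    for stage in CANONICAL_STAGES:
        for i in range(n_per_stage):
            stain = stains[idx % len(stains)]
            subj = idx % n_subjects
            species = "mouse" if subj < n_subjects // 2 else "rat"
            rel_path = f"{stage}_{i:04d}.png"
            cell_rng = np.random.default_rng(root.integers(2**31))
            if render:
                path = out_dir / rel_path
                _, counts, fractions, total = render_cytology_image(
                    stage, params, mix, cell_rng, stain=stain, out_path=path
                )
                path_str = str(path)
            else:
                fractions, total = sample_stage_proportions(stage, mix, cell_rng)
                path_str = str((out_dir or Path("synthetic")) / rel_path)
            records.append(
                ImageRecord(
                    image_path=path_str,
                    subject_id=f"synth{subj:02d}",
                    species=species,
                    strain="synthetic",
                    stain=stain,
                    magnification="20x",
                    lab="synthetic",
                    benchmark_stage=stage,
                    cell_proportions=fractions,
                    total_cells=total,
                    width=params.image_size,
                    height=params.image_size,
                )
            )
            idx += 1
    manifest = DatasetManifest(records=records, provenance=f"synthetic seed={seed}")
    return manifest


def simulate_stage_sequence(
    spec: SequenceSpec, cycle: ArchetypalCycle | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Simulate sample times, true stages and (possibly noisy) labels.

    The true stage at time ``t`` is the archetypal cycle's stage at cycle
    position ``t + true_phase * period``.  After
    ``pseudopregnancy_onset_day`` the animal is locked in diestrus.  Label
    noise replaces a stored label with a uniformly random other canonical
    stage; it never alters the true stage.
    """
    cycle = cycle or default_cycle()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_days * spec.samples_per_day
    times = np.arange(n, dtype=float) / spec.samples_per_day
    true_stages = []
    for t in times:
        if (
            spec.pseudopregnancy_onset_day is not None
            and t >= spec.pseudopregnancy_onset_day
        ):
            true_stages.append("diestrus")
        else:
            true_stages.append(cycle.stage_at(t + spec.true_phase * cycle.period_days))
    observed = []
    for s in true_stages:
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            others = [c for c in CANONICAL_STAGES if c != s]
            observed.append(others[rng.integers(3)])
        else:
            observed.append(s)
    return times, true_stages, observed


def generate_cycle_sequence(
    spec: SequenceSpec,
    cycle: ArchetypalCycle | None = None,
    params: CellRenderParams | None = None,
    mix: StageMixture | None = None,
    out_dir: str | Path | None = None,
    subject_id: str = "synth00",
) -> tuple[DatasetManifest, list[str]]:
    """Generate a sequential multi-day dataset; returns (manifest, true stages).

    Stored ``benchmark_stage`` labels carry the label noise; rendered images
    (and the recorded cell proportions) always follow the true stage.
    Pseudopregnant samples draw leukocyte fractions of at least 0.9.
    """
    cycle = cycle or default_cycle()
    params = params or CellRenderParams()
    mix = mix or StageMixture()
    times, true_stages, observed = simulate_stage_sequence(spec, cycle)
    rng = np.random.default_rng(spec.seed + 1)
    out_dir = Path(out_dir) if out_dir is not None else None
    records = []
    for i, (t, true_stage, label) in enumerate(zip(times, true_stages, observed)):
        pseudo = (
            spec.pseudopregnancy_onset_day is not None
            and t >= spec.pseudopregnancy_onset_day
        )
        floor = 0.9 if pseudo else None
        cell_rng = np.random.default_rng(rng.integers(2**31))
        rel_path = f"seq_{i:04d}.png"
        if out_dir is not None:
            path = out_dir / rel_path
            _, counts, fractions, total = render_cytology_image(
                true_stage, params, mix, cell_rng, out_path=path, min_leukocyte=floor
            )
            path_str = str(path)
        else:
            fractions, total = sample_stage_proportions(
                true_stage, mix, cell_rng, min_leukocyte=floor
            )
            path_str = f"synthetic/{subject_id}/{rel_path}"
        records.append(
            ImageRecord(
                image_path=path_str,
                subject_id=subject_id,
                species="mouse",
                strain="synthetic",
                stain="HE",
                magnification="20x",
                lab="synthetic",
                collected_at=float(t),
                benchmark_stage=label,
                cell_proportions=fractions,
                total_cells=total,
                width=params.image_size,
                height=params.image_size,
            )
        )
    manifest = DatasetManifest(
        records=records, provenance=f"synthetic sequence seed={spec.seed}"
    )
    return manifest, true_stages
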