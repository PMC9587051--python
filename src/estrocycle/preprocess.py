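"""Image preprocessing and dataset preparation.

The pipeline mirrors standard practice for cytology classification with a
fixed-input CNN: luminance-peak alignment, conversion to 3-channel
grayscale, quadrisection into four tiles, randomized augmentation
(reflection / rotation / scale / translation), bilinear resize to
224x224x3, stage balancing, and seeded stratified 80/10/10 splitting.

Quadrisection is applied after splitting so quadrants of one image never
straddle a train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .io import DatasetManifest, ImageRecord
from .stages import CANONICAL_STAGES

logger = logging.getLogger("estrocycle")

LUMINANCE_TARGET = 0.8
LUMINANCE_BINS = 64
INPUT_SHAPE = (224, 224, 3)

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def normalize_luminance(
    img: np.ndarray, target: float = LUMINANCE_TARGET, bins: int = LUMINANCE_BINS
) -> np.ndarray:
    """Align the luminance histogram peak to ``target`` by additive shift.

    The peak is located on a histogram of ``img - img.min()`` with fixed
    bin width ``1/bins`` (64 bins across the unit intensity range) and
    refined as the mean of the values in the modal bin.  Measuring the peak
    relative to the image minimum on fixed-width bins makes the operation
    invariant to pre-clip additive offsets and idempotent (both to
    floating-point precision; idempotence assumes the shifted image needs
    essentially no clipping).  Output is clipped to
    [0, 1].  A constant image maps to ``target``.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    lo = img.min()
    v = img - lo
    hi = v.max()
    if hi == 0:
        return np.full_like(img, float(target))
    width = 1.0 / bins
    edges = np.arange(0.0, hi + width, width)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + width)
    counts, _ = np.histogram(v, bins=edges)
    k = int(np.argmax(counts))
    in_bin = (v >= edges[k]) & ((v < edges[k + 1]) | (k == len(edges) - 2))
    mode = float(v[in_bin].mean())
    shift = (target - lo) - mode
    return np.clip(img + shift, 0.0, 1.0)


def to_three_channel_gray(img: np.ndarray) -> np.ndarray:
    """Collapse RGB to ITU-R 601 luminance and replicate it to 3 channels."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        gray = img
    elif img.ndim == 3 and img.shape[2] == 3:
        gray = img @ _LUMA
    elif img.ndim == 3 and img.shape[2] == 1:
        gray = img[:, :, 0]
    else:
        raise ValueError(f"expected 1- or 3-channel image, got shape {img.shape}")
    return np.repeat(gray[:, :, None], 3, axis=2)


def quadrisect(img: np.ndarray) -> list[np.ndarray]:
    """Split an image into its four quadrants (views tile it exactly).

    Odd dimensions give the extra row/column to the top/left quadrants.
    """
    h, w = img.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2 to quadrisect")
    rh, cw = (h + 1) // 2, (w + 1) // 2
    return [
        img[:rh, :cw],
        img[:rh, cw:],
        img[rh:, :cw],
        img[rh:, cw:],
    ]


def quadrisect_record(record: ImageRecord, out_dir: str | Path) -> list[ImageRecord]:
    """Quadrisect a record's image on disk; quadrants inherit all metadata."""
    import imageio.v3 as iio

    img = iio.imread(record.image_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(record.image_path).stem
    out = []
    for i, quad in enumerate(quadrisect(img)):
        path = out_dir / f"{stem}_q{i}.png"
        iio.imwrite(path, quad)
        out.append(
            record.replace(
                image_path=str(path),
                width=quad.shape[1],
                height=quad.shape[0],
            )
        )
    return out


@dataclass
class AugmentParams:
    """Ranges for the single random transform drawn per augmentation call."""

    reflect: str = "both"  # none | horizontal | vertical | both
    reflect_prob: float = 0.5
    rotation_range: float = 30.0  # degrees, symmetric
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_range: float = 0.1  # fraction of width/height, symmetric
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reflect not in ("none", "horizontal", "vertical", "both"):
            raise ValueError("reflect must be none|horizontal|vertical|both")
        self.scale_range = tuple(self.scale_range)
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale_range must be positive")
        if not 0 <= self.translate_range <= 0.5:
            raise ValueError("translate_range must lie in [0, 0.5]")


class Augmenter:
    """Draws one random reflect/rotate/scale/translate transform per call.

    Deterministic under a fixed seed; edge-replication fill; rotation and
    scaling about the image center.
    """

    def __init__(self, params: AugmentParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)

    def draw(self) -> dict:
        p, rng = self.params, self.rng
        flip_h = p.reflect in ("horizontal", "both") and rng.random() < p.reflect_prob
        flip_v = p.reflect in ("vertical", "both") and rng.random() < p.reflect_prob
        angle = rng.uniform(-p.rotation_range, p.rotation_range) if p.rotation_range else 0.0
        scale = rng.uniform(*p.scale_range) if p.scale_range != (1.0, 1.0) else 1.0
        t = p.translate_range
        tx = rng.uniform(-t, t) if t else 0.0
        ty = rng.uniform(-t, t) if t else 0.0
        return {"flip_h": flip_h, "flip_v": flip_v, "angle": angle, "scale": scale,
                "tx": tx, "ty": ty}

    def apply(self, img: np.ndarray, draw: dict) -> np.ndarray:
        h, w = img.shape[:2]
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        sx = -1.0 if draw["flip_h"] else 1.0
        sy = -1.0 if draw["flip_v"] else 1.0
        core = (
            AffineTransform(scale=(sx * draw["scale"], sy * draw["scale"]))
            + AffineTransform(rotation=np.deg2rad(draw["angle"]))
        )
        tform = (
            AffineTransform(translation=-center)
            + core
            + AffineTransform(translation=center)
            + AffineTransform(translation=(draw["tx"] * w, draw["ty"] * h))
        )
        if np.allclose(tform.params, np.eye(3)):
            return img.astype(float, copy=True)
        return warp(img.astype(float), tform.inverse, mode="edge", order=1,
                    preserve_range=True)

    def __call__(self, img: np.ndarray) -> np.ndarray:
        return self.apply(img, self.draw())


def augment(img: np.ndarray, params: AugmentParams) -> np.ndarray:
    """One-shot augmentation with a fresh generator seeded from ``params``."""
    return Augmenter(params)(img)


def resize_to_input(img: np.ndarray) -> np.ndarray:
    """Bilinear resize of a 3-channel image to the 224x224x3 network input."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {img.shape}")
    if img.shape[:2] == INPUT_SHAPE[:2]:
        return img.copy()
    out = resize(img, INPUT_SHAPE[:2], order=1, anti_aliasing=True,
                 preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def preprocess_image(img: np.ndarray) -> np.ndarray:
    """Full single-image chain: luminance alignment -> 3-channel gray."""
    g3 = to_three_channel_gray(img)
    gn = normalize_luminance(g3[:, :, 0])
    return np.repeat(gn[:, :, None], 3, axis=2)


def balance_stages(manifest: DatasetManifest, seed: int = 0) -> DatasetManifest:
    """Downsample every stage (without replacement) to the minimum count."""
    rng = np.random.default_rng(seed)
    by_stage: dict[str, list[int]] = {s: [] for s in CANONICAL_STAGES}
    for i, r in enumerate(manifest.records):
        if r.benchmark_stage is None:
            raise ValueError(f"record {r.image_path} has no stage label")
        if r.benchmark_stage in by_stage:
            by_stage[r.benchmark_stage].append(i)
    for s, idx in by_stage.items():
        if not idx:
            raise ValueError(f"stage {s!r} has no records; cannot balance")
    n_min = min(len(v) for v in by_stage.values())
    keep: list[int] = []
    for s in CANONICAL_STAGES:
        idx = np.asarray(by_stage[s])
        keep.extend(sorted(rng.choice(idx, size=n_min, replace=False).tolist()))
    keep.sort()
    logger.info("balanced stages to %d records each", n_min)
    return manifest.subset(keep)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test manifests with their target fractions."""

    train: DatasetManifest
    validation: DatasetManifest
    test: DatasetManifest
    fractions: tuple[float, float, float]


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``n`` items to the fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for k in range(rem):
        counts[order[k]] += 1
    return counts


def split_dataset(
    manifest: DatasetManifest,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    strata_keys: Sequence[str] = ("stain", "species", "lab", "magnification"),
    seed: int = 0,
    min_stratum: int = 3,
) -> DatasetSplit:
    """Seeded stratified split (default 80/10/10, proportional per stratum).

    Records are grouped by the joint ``strata_keys`` value; within each
    stratum the fractions hold to within one record (largest-remainder
    rounding).  Strata smaller than ``min_stratum`` fall into a pooled
    global stratum with a logged warning.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise ValueError("fractions must be three values summing to 1")
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[int]] = {}
    for i, r in enumerate(manifest.records):
        key = tuple(getattr(r, k) for k in strata_keys)
        strata.setdefault(key, []).append(i)
    pooled: list[int] = []
    for key in [k for k, v in strata.items() if len(v) < min_stratum]:
        logger.warning("stratum %s has < %d records; pooled globally", key, min_stratum)
        pooled.extend(strata.pop(key))
    if pooled:
        strata[("__pooled__",)] = pooled
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for key in sorted(strata):
        idx = np.asarray(strata[key])
        rng.shuffle(idx)
        counts = _allocate(len(idx), fractions)
        offset = 0
        for part, c in zip(parts, counts):
            part.extend(int(j) for j in idx[offset:offset + c])
            offset += c
    train, val, test = (sorted(p) for p in parts)
    logger.info("split %d records into %d/%d/%d", len(manifest), len(train),
                len(val), len(test))
    return DatasetSplit(
        train=manifest.subset(train, provenance=manifest.provenance + " [train]"),
        validation=manifest.subset(val, provenance=manifest.provenance + " [val]"),
        test=manifest.subset(test, provenance=manifest.provenance + " [test]"),
        fractions=fractions,
    )
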