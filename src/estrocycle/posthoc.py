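"""Post-hoc layer over the softmax: confidence, cycle fitting and flags.

Confidence Index
    CI = (P_max - P_max-1) / (P_max + P_max-1), the normalized margin
    between the two largest softmax probabilities.  CI = 1 when all mass is
    on one stage; CI = 0 when the top two stages tie.

Archetypal cycle
    A periodic waveform mapping time (days) to the numeric stage encoding
    (D=0.5, P=1.5, E=2.5, M=3.5; 0.0 = 4.0 = metestrus/diestrus boundary)
    over a 4.8-day period, built through the temporal midpoint of each
    stage.  A sequence of classifications is fitted by shifting the phase in
    0.1-cycle increments and keeping the shift with the maximum Pearson
    correlation between observed stage numbers and the waveform.

Cycle disruption flags
    A pseudopregnancy warning when the current diestrus run exceeds the
    previous cycles' runs by more than 50%, and an anestrus flag when more
    than two consecutive days show >90% leukocytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .io import CellCounts
from .results import ClassificationResult, StageProbabilities
from .stages import (
    CANONICAL_STAGES,
    boundary_transition,
    normalize_stage,
    number_to_stage,
    stage_to_number,
)

logger = logging.getLogger("estrocycle")

DEFAULT_STAGE_FRACTIONS = {
    # Duration of each stage as a fraction of the cycle.  These are
    # config-overridable defaults chosen to respect the usual ordering
    # (diestrus longest, proestrus shortest); they are not measured values.
    "diestrus": 0.35,
    "proestrus": 0.15,
    "estrus": 0.30,
    "metestrus": 0.20,
}


def confidence_index(p: StageProbabilities | Sequence[float]) -> float:
    """Normalized margin between the two largest stage probabilities."""
    probs = np.asarray(p.probs if isinstance(p, StageProbabilities) else p, dtype=float)
    if probs.size < 2:
        raise ValueError("need at least two stage probabilities")
    if np.any(probs < 0):
        raise ValueError("probabilities must be non-negative")
    top = np.sort(probs)[::-1]
    p_max, p_runner = top[0], top[1]
    if p_max + p_runner == 0:
        raise ValueError("not a probability vector (all-zero top entries)")
    return float((p_max - p_runner) / (p_max + p_runner))


@dataclass
class ArchetypalCycle:
    """The canonical periodic stage waveform of the estrous cycle."""

    period_days: float = 4.8
    stage_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS)
    )
    phase_increment: float = 0.1
    mode: str = "interp"  # or "sinusoid"
    _waveform: Callable = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fracs = [self.stage_fractions[s] for s in CANONICAL_STAGES]
        if any(f <= 0 for f in fracs):
            raise ValueError("stage fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValueError(f"stage fractions must sum to 1 (got {sum(fracs):.8f})")
        if self.mode not in ("interp", "sinusoid"):
            raise ValueError("waveform mode must be 'interp' or 'sinusoid'")
        self._waveform = self._build()

    def boundaries(self) -> dict[str, tuple[float, float]]:
        """(start, end) time in days of each stage within one period."""
        out, t = {}, 0.0
        for s in CANONICAL_STAGES:
            dur = self.stage_fractions[s] * self.period_days
            out[s] = (t, t + dur)
            t += dur
        return out

    def midpoints(self) -> dict[str, float]:
        return {s: (a + b) / 2 for s, (a, b) in self.boundaries().items()}

    def _anchors(self) -> tuple[np.ndarray, np.ndarray]:
        mids = self.midpoints()
        t = np.array([0.0] + [mids[s] for s in CANONICAL_STAGES] + [self.period_days])
        v = np.array([0.0, 0.5, 1.5, 2.5, 3.5, 4.0])
        return t, v

    def _build(self) -> Callable:
        t, v = self._anchors()
        if self.mode == "interp":
            interp = PchipInterpolator(t, v)
            return lambda x: np.asarray(interp(x))
        # two-term Fourier alternative: a*sin + b*cos + c, least squares on anchors
        w = 2 * np.pi / self.period_days
        design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        return lambda x: (
            coef[0] * np.sin(w * np.asarray(x))
            + coef[1] * np.cos(w * np.asarray(x))
            + coef[2]
        )

    def waveform(self, t):
        """Stage-number value of the cycle at time ``t`` days (periodic)."""
        t = np.asarray(t, dtype=float) % self.period_days
        out = self._waveform(t)
        return float(out) if out.ndim == 0 else out

    def stage_at(self, t) -> str:
        return number_to_stage(self.waveform(t))


def default_cycle(**kw) -> ArchetypalCycle:
    return ArchetypalCycle(**kw)


def build_archetypal_cycle(
    stage_fractions: dict[str, float] | Sequence[float],
    period_days: float = 4.8,
    mode: str = "interp",
) -> ArchetypalCycle:
    """Construct the archetypal cycle from per-stage duration fractions."""
    if not isinstance(stage_fractions, dict):
        stage_fractions = dict(zip(CANONICAL_STAGES, stage_fractions))
    return ArchetypalCycle(
        period_days=period_days, stage_fractions=stage_fractions, mode=mode
    )


def circular_stage_distance(a, b) -> np.ndarray:
    """Distance between stage numbers on the 4-unit circle (M and D adjacent)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 4.0
    return np.minimum(d, 4.0 - d)


@dataclass
class CycleFitResult:
    """Outcome of the phase-shift grid search."""

    best_phase: float
    pearson_r: float
    phases: np.ndarray
    r_by_phase: np.ndarray
    outlier_indices: list[int]
    cycle: ArchetypalCycle

    def to_dict(self) -> dict:
        return {
            "best_phase": self.best_phase,
            "pearson_r": self.pearson_r,
            "phases": [float(p) for p in self.phases],
            "r_by_phase": [float(r) for r in self.r_by_phase],
            "outlier_indices": list(self.outlier_indices),
            "period_days": self.cycle.period_days,
        }


def fit_cycle_phase(
    times: Sequence[float],
    stages: Sequence[str],
    cycle: ArchetypalCycle | None = None,
    deviation_threshold: float = 1.0,
    correlation: str = "discrete",
) -> CycleFitResult:
    """Fit the archetypal cycle's phase to a sequence of classifications.

    Requires more than four days of data (n > 4x at sampling frequency x
    per day).  For each grid phase the Pearson correlation between the
    observed stage numbers and the phase-shifted waveform is computed; the
    argmax wins (ties toward the smaller phase).  Samples whose stage number
    deviates from the fitted waveform by more than ``deviation_threshold``
    (circular distance, modulo 4) are flagged as outliers.

    ``correlation="discrete"`` (default) correlates the labels against the
    waveform's own stage numbers (the discretized waveform): observations
    are stage labels, and correlating them against the continuous waveform
    value biases the fitted phase when stage durations are unequal.
    ``correlation="continuous"`` uses the raw waveform values instead.
    """
    if correlation not in ("discrete", "continuous"):
        raise ValueError("correlation must be 'discrete' or 'continuous'")
    cycle = cycle or default_cycle()
    times = np.asarray(times, dtype=float)
    n = times.size
    if n < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    samples_per_day = 1.0 / float(np.median(np.diff(times)))
    if n <= 4 * samples_per_day:
        raise ValueError(
            "cycle fitting needs more than 4 days of data "
            f"(n={n}, sampling frequency ~{samples_per_day:.2f}/day); "
            "collect a longer sequence"
        )
    y = np.array([stage_to_number(s) for s in stages], dtype=float)
    if np.std(y) == 0:
        raise ValueError("degenerate sequence: constant stage labels")
    phases = np.round(
        np.arange(0.0, 1.0 - 1e-9, cycle.phase_increment), 10
    )
    def waveform_series(phi: float) -> np.ndarray:
        w = np.atleast_1d(cycle.waveform(times + phi * cycle.period_days))
        if correlation == "discrete":
            w = np.floor(w % 4.0) + 0.5
        return w

    r_values = np.empty(phases.size)
    for i, phi in enumerate(phases):
        w = waveform_series(phi)
        if np.std(w) == 0:
            raise ValueError("degenerate sequence: constant waveform values")
        r_values[i] = np.corrcoef(y, w)[0, 1]
    best = int(np.argmax(r_values))  # argmax returns the first (smallest) phase on ties
    best_phase = float(phases[best])
    residuals = circular_stage_distance(y, waveform_series(best_phase))
    outliers = [int(i) for i in np.nonzero(residuals > deviation_threshold)[0]]
    return CycleFitResult(
        best_phase=best_phase,
        pearson_r=float(r_values[best]),
        phases=phases,
        r_by_phase=r_values,
        outlier_indices=outliers,
        cycle=cycle,
    )


def resolve_prediction(
    net: ClassificationResult,
    fit: CycleFitResult,
    time: float,
    ci_threshold: float = 0.30,
) -> ClassificationResult:
    """Combine the net classification with the fitted cycle position.

    Agreement passes the net stage through untouched.  Disagreement with a
    confident net (CI >= threshold) raises the outlier flag and keeps the
    net stage (the interactive choice the GUI offers is deferred to the
    caller).  Disagreement with a low CI suggests the transition stage
    between the two stages nearest the fitted waveform position.
    """
    cycle = fit.cycle
    position = cycle.waveform(time + fit.best_phase * cycle.period_days)
    cyc_stage = number_to_stage(position)
    out = net.replace(cyclicity_stage=cyc_stage, cycle_phase=fit.best_phase)
    if normalize_stage(net.stage) == cyc_stage:
        return out
    if net.confidence_index >= ci_threshold:
        logger.info(
            "outlier flag: net=%s cycle=%s CI=%.3f", net.stage, cyc_stage,
            net.confidence_index,
        )
        return out.replace(outlier_flag=True)
    suggestion = boundary_transition(round(position))
    logger.info(
        "transition suggestion %s: net=%s cycle=%s CI=%.3f",
        suggestion, net.stage, cyc_stage, net.confidence_index,
    )
    return out.replace(transition_suggestion=suggestion)


@dataclass
class PseudopregnancyResult:
    flag: bool
    status: str  # "flagged" | "ok" | "insufficient history"
    onset_index: int | None = None
    baseline_days: float | None = None


def detect_pseudopregnancy(
    times: Sequence[float],
    stages: Sequence[str],
    min_history_cycles: int = 1,
    factor: float = 1.5,
) -> PseudopregnancyResult:
    """Flag abnormally long diestrus runs against the animal's own history.

    Consecutive diestrus samples form runs whose duration (days) is the
    sample count times the typical sampling interval.  A run is flagged at
    the first sample where its running duration strictly exceeds
    ``factor`` x mean duration of the previous completed runs; at least
    ``min_history_cycles`` completed prior runs are required.
    """
    times = np.asarray(times, dtype=float)
    labels = [normalize_stage(s) for s in stages]
    if times.size == 0:
        return PseudopregnancyResult(False, "insufficient history")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0

    runs: list[tuple[int, int]] = []  # (start, end) inclusive sample indices
    start = None
    for i, s in enumerate(labels):
        if s == "diestrus":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    open_run = start is not None
    if open_run:
        runs.append((start, len(labels) - 1))

    history: list[float] = []
    for ri, (a, b) in enumerate(runs):
        is_complete = ri < len(runs) - 1 or not open_run
        if len(history) >= min_history_cycles:
            threshold = factor * float(np.mean(history))
            for j in range(a, b + 1):
                duration = (j - a + 1) * dt
                if duration > threshold:
                    return PseudopregnancyResult(
                        True, "flagged", onset_index=j,
                        baseline_days=float(np.mean(history)),
                    )
        if is_complete:
            history.append((b - a + 1) * dt)
    # the current (last) run needs min_history_cycles completed runs before it
    n_prior = max(0, len(runs) - 1)
    if n_prior < min_history_cycles:
        return PseudopregnancyResult(False, "insufficient history")
    return PseudopregnancyResult(
        False, "ok",
        baseline_days=float(np.mean(history[:n_prior])) if history else None,
    )


@dataclass
class AnestrusResult:
    flag: bool
    start_index: int | None = None
    end_index: int | None = None


def detect_anestrus_from_counts(
    times: Sequence[float],
    counts: Sequence[CellCounts],
    leuk_threshold: float = 0.9,
    min_days: float = 2.0,
) -> AnestrusResult:
    """Flag an anestrous state from persistent leukocyte dominance.

    The flag is raised iff some consecutive span with leukocyte fraction
    strictly above ``leuk_threshold`` lasts strictly longer than
    ``min_days`` (span duration = sample count x typical interval).
    """
    times = np.asarray(times, dtype=float)
    if times.size != len(counts):
        raise ValueError("times and counts must be aligned")
    if times.size == 0:
        return AnestrusResult(False)
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    high = [c.leukocyte_frac > leuk_threshold for c in counts]
    start = None
    for i, h in enumerate(high + [False]):
        if h and start is None:
            start = i
        elif not h and start is not None:
            duration = (i - start) * dt
            if duration > min_days:
                return AnestrusResult(True, start_index=start, end_index=i - 1)
            start = None
    return AnestrusResult(False)
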