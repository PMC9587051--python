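"""Classifier evaluation: confusion matrices, ROC, bootstrap, exact tests.

One-vs-rest ROC curves are empirical (every softmax score is a threshold)
with trapezoidal auROC.  Accuracy distributions come from joint bootstrap
resampling of (truth, prediction) pairs.  Accuracy comparisons between two
classifiers use Fisher's exact test on the 2x2 correct/incorrect table with
a Woolf (log-odds) confidence interval.  Grouped k-fold cross-validation
partitions group values (subjects, stains, species), never records, so no
group leaks between a fold's training and test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import DatasetManifest
from .results import StageProbabilities
from .stages import CANONICAL_STAGES, normalize_stage

logger = logging.getLogger("estrocycle")


def confusion_matrix(
    truth: Sequence[str],
    pred: Sequence[str],
    stage_names: Sequence[str] = CANONICAL_STAGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (rows = true stage, columns = predicted) and row-normalized.

    Row-normalized entries of empty rows are zero.
    """
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    t = [normalize_stage(s) for s in truth]
    p = [normalize_stage(s) for s in pred]
    for s in t + p:
        if s not in stage_names:
            raise ValueError(f"label {s!r} outside the stage set {tuple(stage_names)}")
    counts = _sk_confusion(t, p, labels=list(stage_names))
    counts_df = pd.DataFrame(counts, index=stage_names, columns=stage_names)
    row_sums = counts_df.sum(axis=1).replace(0, 1)
    return counts_df, counts_df.div(row_sums, axis=0)


def one_vs_rest_roc(
    scores: Sequence[StageProbabilities] | np.ndarray,
    truth: Sequence[str],
    stage: str,
    stage_names: Sequence[str] = CANONICAL_STAGES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Empirical ROC for one stage's probability; returns (fpr, tpr, thresholds, auroc).

    The positive class is ``truth == stage``; the score is that stage's
    softmax probability.  The curve runs from (0,0) to (1,1) and the auROC
    is its trapezoidal integral.
    """
    stage = normalize_stage(stage)
    y = np.asarray([normalize_stage(s) == stage for s in truth], dtype=int)
    if y.all() or not y.any():
        raise ValueError(f"both classes must be present for stage {stage!r}")
    if isinstance(scores[0], StageProbabilities):
        j = list(stage_names).index(stage)
        s = np.asarray([p.probs[j] for p in scores], dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auroc


@dataclass
class SensSpecResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    crossing: float
    sensitivity_se: np.ndarray | None = None
    specificity_se: np.ndarray | None = None


def sens_spec_cutoff(
    scores: Sequence[float],
    truth: Sequence[int] | Sequence[bool],
    n_boot: int = 0,
    seed: int = 0,
) -> SensSpecResult:
    """Sensitivity/specificity vs threshold and their crossing point.

    A sample is called positive when its score is >= the threshold.  The
    grid is the sorted unique scores plus the endpoints {0, 1}; the crossing
    is located by linear interpolation between the adjacent grid points
    where sensitivity - specificity changes sign.  Optional bootstrap
    standard-error bands.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    grid = np.unique(np.concatenate([[0.0], np.unique(s), [1.0]]))

    def curves(sv, yv):
        sens = np.array([(sv[yv] >= t).mean() for t in grid])
        spec = np.array([(sv[~yv] < t).mean() for t in grid])
        return sens, spec

    sens, spec = curves(s, y)
    diff = sens - spec
    crossing = grid[-1]
    for i in range(len(grid) - 1):
        if diff[i] == 0:
            crossing = float(grid[i])
            break
        if diff[i] * diff[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossing = float(grid[i] + frac * (grid[i + 1] - grid[i]))
            break
        if diff[i + 1] == 0:
            crossing = float(grid[i + 1])
            break
    sens_se = spec_se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots_sens, boots_spec = [], []
        for _ in range(n_boot):
            idx = rng.integers(len(s), size=len(s))
            if y[idx].all() or not y[idx].any():
                continue
            bs, bp = curves(s[idx], y[idx])
            boots_sens.append(bs)
            boots_spec.append(bp)
        sens_se = np.std(boots_sens, axis=0, ddof=1)
        spec_se = np.std(boots_spec, axis=0, ddof=1)
    return SensSpecResult(grid, sens, spec, crossing, sens_se, spec_se)


@dataclass
class BootstrapResult:
    accuracies: np.ndarray
    mean: float
    q25: float
    q75: float
    iqr: float
    bar_low: float  # 25th percentile minus the IQR
    bar_high: float  # 75th percentile plus the IQR


def bootstrap_accuracy(
    truth: Sequence[str],
    pred: Sequence[str],
    n_iter: int = 5000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the accuracy by resampling (truth, pred) pairs jointly.

    Error bars follow the 25th/75th percentile +/- IQR convention; the
    plain quartiles are also reported.
    """
    t = np.asarray([normalize_stage(s) for s in truth])
    p = np.asarray([normalize_stage(s) for s in pred])
    if t.size != p.size or t.size == 0:
        raise ValueError("truth and pred must be equal-length and non-empty")
    correct = (t == p).astype(float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(t.size, size=(n_iter, t.size))
    accs = correct[idx].mean(axis=1)
    q25, q75 = np.percentile(accs, [25, 75])
    iqr = q75 - q25
    return BootstrapResult(
        accuracies=accs, mean=float(accs.mean()), q25=float(q25), q75=float(q75),
        iqr=float(iqr), bar_low=float(q25 - iqr), bar_high=float(q75 + iqr),
    )


@dataclass
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact_comparison(
    correct_a: int, n_a: int, correct_b: int, n_b: int
) -> FisherResult:
    """Fisher's exact test comparing two classifiers' accuracy.

    The 2x2 table is [[correct_a, n_a - correct_a], [correct_b,
    n_b - correct_b]].  The two-sided p comes from the hypergeometric
    distribution; the odds ratio is the sample (a*d)/(b*c) with a Woolf
    log-OR 95% interval (0.5 added to every cell when any cell is zero).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("both groups must be non-empty")
    if not (0 <= correct_a <= n_a and 0 <= correct_b <= n_b):
        raise ValueError("correct counts must lie within group sizes")
    a, b = correct_a, n_a - correct_a
    c, d = correct_b, n_b - correct_b
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    log_or = np.log((cells[0] * cells[3]) / (cells[1] * cells[2]))
    se = float(np.sqrt(np.sum(1.0 / cells)))
    ci_low, ci_high = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    return FisherResult(
        odds_ratio=float(odds), ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=float(p), table=((a, b), (c, d)),
    )


@dataclass
class GroupedKFoldReport:
    per_fold_accuracy: list[float]
    mean_accuracy: float
    mean_confusion: pd.DataFrame
    fold_groups: list[list]


def grouped_kfold_oos(
    manifest: DatasetManifest,
    group_key: str,
    trainer: Callable[[DatasetManifest], Callable[[DatasetManifest], Sequence[str]]],
    k: int = 6,
    seed: int = 0,
    mode: str = "kfold",
    stage_names: Sequence[str] = CANONICAL_STAGES,
) -> GroupedKFoldReport:
    """Out-of-sample evaluation with folds over GROUP values, not records.

    ``trainer(train_manifest)`` must return a prediction callable mapping a
    manifest to stage labels.  With ``mode="leave_one_out"`` each distinct
    category (e.g. each stain) is held out in turn, matching out-of-sample
    stain/species testing; otherwise group values are shuffled into ``k``
    near-equal folds.  The reported confusion matrix is the element-wise
    mean of the per-fold matrices.
    """
    values = sorted({getattr(r, group_key) for r in manifest})
    if mode == "leave_one_out":
        folds = [[v] for v in values]
    else:
        if len(values) < k:
            raise ValueError(
                f"only {len(values)} distinct {group_key} values; use k <= {len(values)}"
            )
        rng = np.random.default_rng(seed)
        shuffled = list(values)
        rng.shuffle(shuffled)
        folds = [list(shuffled[i::k]) for i in range(k)]
    accs, matrices, fold_groups = [], [], []
    for fold in folds:
        fold_set = set(fold)
        test_idx = [i for i, r in enumerate(manifest.records)
                    if getattr(r, group_key) in fold_set]
        train_idx = [i for i, r in enumerate(manifest.records)
                     if getattr(r, group_key) not in fold_set]
        train_m = manifest.subset(train_idx)
        test_m = manifest.subset(test_idx)
        assert not ({getattr(r, group_key) for r in train_m}
                    & {getattr(r, group_key) for r in test_m})
        predict = trainer(train_m)
        preds = list(predict(test_m))
        truth = [r.benchmark_stage for r in test_m]
        counts, _ = confusion_matrix(truth, preds, stage_names)
        matrices.append(counts)
        accs.append(float(np.mean([t == p for t, p in zip(truth, preds)])))
        fold_groups.append(fold)
        logger.info("fold %s: accuracy %.3f on %d records", fold, accs[-1], len(test_m))
    mean_conf = sum(matrices) / len(matrices)
    return GroupedKFoldReport(
        per_fold_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        mean_confusion=mean_conf,
        fold_groups=fold_groups,
    )


@dataclass
class EvaluationReport:
    """Bundle of the standard evaluation outputs for one prediction set."""

    confusion: pd.DataFrame
    confusion_normalized: pd.DataFrame
    accuracy: float
    per_stage_accuracy: dict[str, float]
    auroc: dict[str, float]
    bootstrap: BootstrapResult | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "confusion_normalized": self.confusion_normalized.to_dict(),
            "accuracy": self.accuracy,
            "per_stage_accuracy": self.per_stage_accuracy,
            "auroc": self.auroc,
            "bootstrap_mean": None if self.bootstrap is None else self.bootstrap.mean,
            "bootstrap_bars": None if self.bootstrap is None else
                [self.bootstrap.bar_low, self.bootstrap.bar_high],
        }


def evaluate_predictions(
    truth: Sequence[str],
    pred: Sequence[str],
    scores: Sequence[StageProbabilities] | None = None,
    stage_names: Sequence[str] = CANONICAL_STAGES,
    n_boot: int = 0,
    seed: int = 0,
) -> EvaluationReport:
    """Compose confusion, accuracy, per-stage auROC and optional bootstrap."""
    counts, norm = confusion_matrix(truth, pred, stage_names)
    total = counts.values.sum()
    accuracy = float(np.trace(counts.values) / total) if total else float("nan")
    per_stage = {
        s: float(norm.loc[s, s]) if counts.loc[s].sum() > 0 else float("nan")
        for s in stage_names
    }
    auroc = {}
    if scores is not None:
        for s in stage_names:
            try:
                *_, a = one_vs_rest_roc(scores, truth, s, stage_names)
                auroc[s] = a
            except ValueError:
                auroc[s] = float("nan")
    boot = bootstrap_accuracy(truth, pred, seed=seed, n_iter=n_boot) if n_boot else None
    return EvaluationReport(
        confusion=counts, confusion_normalized=norm, accuracy=accuracy,
        per_stage_accuracy=per_stage, auroc=auroc, bootstrap=boot,
    )
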