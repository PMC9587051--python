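"""Result containers shared between the classifier and post-hoc layers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .stages import CANONICAL_STAGES, normalize_stage


@dataclass(frozen=True)
class StageProbabilities:
    """A softmax probability vector aligned to a fixed stage ordering.

    The default ordering is the canonical (D, P, E, M); models with extra or
    merged stages carry their own ordering.  The two largest entries are the
    P_max / P_max-1 pair the Confidence Index is computed from.
    """

    probs: tuple[float, ...]
    stages: tuple[str, ...] = CANONICAL_STAGES

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.stages):
            raise ValueError("probability vector length != number of stages")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum():.8f})")
        object.__setattr__(self, "probs", tuple(float(v) for v in p))

    @property
    def p_max(self) -> float:
        return float(np.sort(self.probs)[-1])

    @property
    def p_runner_up(self) -> float:
        return float(np.sort(self.probs)[-2])

    def top_stage(self) -> str:
        """Argmax stage; ties broken by position in the stage ordering."""
        return self.stages[int(np.argmax(self.probs))]

    def second_stage(self) -> str:
        order = np.argsort(-np.asarray(self.probs), kind="stable")
        return self.stages[int(order[1])]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.stages, self.probs))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "StageProbabilities":
        stages = tuple(d.keys())
        return cls(probs=tuple(float(v) for v in d.values()), stages=stages)


@dataclass
class ClassificationResult:
    """One image's final classification with confidence and post-hoc flags."""

    image_path: str
    stage: str
    probabilities: StageProbabilities
    confidence_index: float
    cyclicity_stage: str | None = None
    outlier_flag: bool = False
    transition_suggestion: str | None = None
    pseudopregnancy_flag: bool = False
    cycle_phase: float | None = None

    def __post_init__(self) -> None:
        self.stage = normalize_stage(self.stage)
        if not 0.0 <= self.confidence_index <= 1.0 + 1e-12:
            raise ValueError("confidence index must lie in [0, 1]")

    def replace(self, **kw) -> "ClassificationResult":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "image_path": self.image_path,
            "stage": self.stage,
            "probabilities": self.probabilities.as_dict(),
            "confidence_index": self.confidence_index,
            "cyclicity_stage": self.cyclicity_stage,
            "outlier_flag": self.outlier_flag,
            "transition_suggestion": self.transition_suggestion,
            "pseudopregnancy_flag": self.pseudopregnancy_flag,
            "cycle_phase": self.cycle_phase,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassificationResult":
        return cls(
            image_path=d["image_path"],
            stage=d["stage"],
            probabilities=StageProbabilities.from_dict(d["probabilities"]),
            confidence_index=float(d["confidence_index"]),
            cyclicity_stage=d.get("cyclicity_stage"),
            outlier_flag=bool(d.get("outlier_flag", False)),
            transition_suggestion=d.get("transition_suggestion"),
            pseudopregnancy_flag=bool(d.get("pseudopregnancy_flag", False)),
            cycle_phase=d.get("cycle_phase"),
        )
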