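"""Estrous stage labels, aliases and the numeric stage encoding.

The rodent estrous cycle has four canonical stages in cyclic order
diestrus -> proestrus -> estrus -> metestrus -> diestrus.  For cycle
fitting each stage is encoded by the midpoint of a unit interval:
D=0.5, P=1.5, E=2.5, M=3.5, with 0.0 (equivalently 4.0) naming the
metestrus/diestrus transition.
"""

from __future__ import annotations

DIESTRUS = "diestrus"
PROESTRUS = "proestrus"
ESTRUS = "estrus"
METESTRUS = "metestrus"

#: canonical cyclic order (D -> P -> E -> M -> D)
CANONICAL_STAGES: tuple[str, ...] = (DIESTRUS, PROESTRUS, ESTRUS, METESTRUS)

#: transition labels between cyclically adjacent stages, in cycle order
TRANSITION_LABELS: tuple[str, ...] = (
    "metestrus/diestrus",
    "diestrus/proestrus",
    "proestrus/estrus",
    "estrus/metestrus",
)

_STAGE_NUMBERS = {DIESTRUS: 0.5, PROESTRUS: 1.5, ESTRUS: 2.5, METESTRUS: 3.5}

# transitions sit on the integer boundaries of the encoding
_TRANSITION_NUMBERS = {
    "metestrus/diestrus": 0.0,
    "diestrus/proestrus": 1.0,
    "proestrus/estrus": 2.0,
    "estrus/metestrus": 3.0,
}

_ALIASES = {
    "d": DIESTRUS,
    "di": DIESTRUS,
    "diestrus": DIESTRUS,
    "p": PROESTRUS,
    "pro": PROESTRUS,
    "proestrus": PROESTRUS,
    "e": ESTRUS,
    "es": ESTRUS,
    "estrus": ESTRUS,
    "m": METESTRUS,
    "met": METESTRUS,
    "metestrus": METESTRUS,
}


def normalize_stage(label: str) -> str:
    """Map a stage label or common alias (e.g. ``"E"``) to its canonical name.

    Transition labels written as ``"a/b"`` are normalized component-wise and
    returned in canonical cycle order.  Raises ``ValueError`` for anything
    that is not a recognizable stage.
    """
    s = str(label).strip().lower()
    if "/" in s:
        a, b = (part.strip() for part in s.split("/", 1))
        a, b = normalize_stage(a), normalize_stage(b)
        for t in TRANSITION_LABELS:
            if set(t.split("/")) == {a, b}:
                return t
        raise ValueError(f"stages {a!r} and {b!r} are not cyclically adjacent")
    if s in _ALIASES:
        return _ALIASES[s]
    raise ValueError(f"unrecognized stage label: {label!r}")


def is_transition(label: str) -> bool:
    return "/" in str(label)


def flanking_stages(transition: str) -> tuple[str, str]:
    """The two canonical stages a transition label sits between."""
    t = normalize_stage(transition)
    if not is_transition(t):
        raise ValueError(f"{transition!r} is not a transition label")
    a, b = t.split("/")
    return a, b


def stage_to_number(stage: str) -> float:
    """Numeric encoding of a stage (D=0.5, P=1.5, E=2.5, M=3.5).

    Transition labels map to the integer boundary between their flanking
    stages (metestrus/diestrus = 0.0).
    """
    s = normalize_stage(stage)
    if is_transition(s):
        return _TRANSITION_NUMBERS[s]
    return _STAGE_NUMBERS[s]


def number_to_stage(x: float, as_transition_at_integer: bool = False) -> str:
    """Invert the numeric encoding: [0,1)->D, [1,2)->P, [2,3)->E, [3,4)->M.

    Values outside [0, 4) are reduced modulo 4.  When
    ``as_transition_at_integer`` is set, exact integer positions return the
    transition label of that boundary (0.0 -> "metestrus/diestrus").
    """
    v = float(x) % 4.0
    if as_transition_at_integer and v == int(v):
        return TRANSITION_LABELS[int(v)]
    return CANONICAL_STAGES[int(v)]


def transition_between(a: str, b: str) -> str:
    """Transition label joining two cyclically adjacent canonical stages."""
    return normalize_stage(f"{a}/{b}")


def boundary_transition(k: int) -> str:
    """Transition label of integer boundary ``k`` of the stage encoding."""
    return TRANSITION_LABELS[int(k) % 4]
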