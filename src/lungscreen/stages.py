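"""TNM-derived stage ladder used throughout the model.

Lung cancers progress through the ordered sub-stages IA, IB, IIA, IIB, IIIA,
IIIB, IV in numerical order without skipping.  Broad stages I-IV group the
sub-stages for utilities and reporting; "early" diagnosis means broad stage
I or II.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV")
N_STAGES: int = len(STAGES)
N_TRANSITIONS: int = N_STAGES - 1  # stage IV has no onward progression

BROAD_STAGE: dict[str, str] = {
    "IA": "I", "IB": "I",
    "IIA": "II", "IIB": "II",
    "IIIA": "III", "IIIB": "III",
    "IV": "IV",
}

#: indices of stages counted as an "early" (broad stage I/II) diagnosis
EARLY_STAGE_INDICES: frozenset[int] = frozenset(
    i for i, s in enumerate(STAGES) if BROAD_STAGE[s] in ("I", "II")
)


def stage_index(stage: str) -> int:
    """Position of ``stage`` on the ladder (0 = IA ... 6 = IV)."""
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


def is_early(stage: str | int) -> bool:
    """True if the stage maps to broad stage I or II."""
    idx = stage if isinstance(stage, int) else stage_index(stage)
    return idx in EARLY_STAGE_INDICES
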