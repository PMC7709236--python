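"""Death resolution with the conservative lead-time / stage-shift link.

Post-diagnosis survival depends only on stage at diagnosis.  A single uniform
quantile per individual is mapped through the stage-specific inverse CDF in
both arms (common-quantile coupling), so that pathwise:

* detection earlier but at the SAME stage confers no survival benefit — both
  arms share one lung-cancer death date (this mitigates lead-time bias);
* detection at an EARLIER stage extends survival through the stage-specific
  distribution, but the lung-cancer death date is clamped to be no earlier
  than the control arm's (screening cannot be less effective than no
  screening);
* a screen-detected case whose control counterpart never presents before
  other-cause death is over-diagnosis: no lung-cancer death in either arm.

Realised death is the earlier of the lung-cancer death candidate and
other-cause death; lung-cancer death is always preceded by a diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import SurvivalParams
from .screening import DiagnosisRecord, ScreenEvent

INF = float("inf")


@dataclass
class PersonOutcome:
    """One simulant's realised history under one arm (times from entry)."""

    arm: str                              # "screening" | "control"
    screens: list[ScreenEvent] = field(default_factory=list)
    diagnosis: DiagnosisRecord | None = None
    death_time: float = INF
    death_cause: str = "other"            # "lung_cancer" | "other"
    lead_time: float | None = None
    overdiagnosed: bool = False


def sample_survival_from_diagnosis(stage: int, sp: SurvivalParams, quantile: float) -> float:
    """Inverse-CDF survival draw for a given stage at diagnosis.

    The same quantile reused across stages/arms makes survival monotone in
    stage pathwise (earlier stage => longer or equal survival).
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError(f"quantile must be in (0,1), got {quantile}")
    if sp.family != "exponential":
        raise NotImplementedError(f"survival family {sp.family!r}")
    return -math.log1p(-quantile) / sp.rate[stage]


def resolve_death(dx_screening: DiagnosisRecord | None,
                  dx_control: DiagnosisRecord | None,
                  oc_death: float, sp: SurvivalParams,
                  quantile: float) -> tuple[PersonOutcome, PersonOutcome]:
    """Resolve CRN-paired death times/causes for the two arms.

    ``oc_death`` is the (shared) other-cause death time from entry; both
    diagnosis records must come from the same latent course.
    """
    if dx_control is not None and dx_screening is not None:
        if dx_screening.mode != "screen_detected" and (
                dx_screening.time != dx_control.time or
                dx_screening.stage != dx_control.stage):
            raise ValueError("inconsistent pairing: non-screen diagnoses must match control")

    cand_control = INF
    if dx_control is not None:
        cand_control = dx_control.time + sample_survival_from_diagnosis(
            dx_control.stage, sp, quantile)

    cand_screening = INF
    if dx_screening is not None:
        if dx_control is not None and dx_screening.stage == dx_control.stage:
            cand_screening = cand_control  # same stage: no survival benefit
        else:
            raw = dx_screening.time + sample_survival_from_diagnosis(
                dx_screening.stage, sp, quantile)
            # screening cannot be less effective than no screening
            cand_screening = max(raw, cand_control) if dx_control is not None else INF
            if dx_control is None:
                # over-diagnosis: control never diagnosed before other-cause
                # death, so no lung-cancer death is allowed in either arm
                cand_screening = INF

    def _outcome(arm: str, dx: DiagnosisRecord | None, cand: float) -> PersonOutcome:
        if cand <= oc_death and dx is not None:
            return PersonOutcome(arm=arm, diagnosis=dx, death_time=cand,
                                 death_cause="lung_cancer")
        return PersonOutcome(arm=arm, diagnosis=dx, death_time=oc_death,
                             death_cause="other")

    out_s = _outcome("screening", dx_screening, cand_screening)
    out_c = _outcome("control", dx_control, cand_control)

    if dx_screening is not None and dx_control is not None:
        out_s.lead_time = dx_control.time - dx_screening.time
    elif dx_screening is not None:
        out_s.lead_time = None
    out_s.overdiagnosed = dx_screening is not None and dx_control is None
    return out_s, out_c
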