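"""Screening programme designs, eligibility, participation and the LDCT pathway.

Four programme designs are modelled:

* S — a single one-off screen shortly after entry (offset 0);
* T — a triple screen at entry and at 12 and 24 months (not age-capped);
* A — annual screens from entry, stopping strictly before the 80th birthday;
* B — biennial screens from entry, with the same age cap.

Crossed with four entry-age windows (55-80, 60-80, 55-75, 60-75; inclusive
bounds) and three minimum predicted-risk thresholds (>= 3%, 4%, 5%) this
yields the 48 intervention strategies; "none" is the no-screening comparator.

The LDCT test is a binary sensitivity/specificity gate, independent of stage
and tumour characteristics; false-positive and indeterminate results are
treated equivalently (workup cost and temporary disutility, never a
diagnosis).  Participation is full-concordance: joiners attend every
scheduled screen they survive to, until diagnosed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .natural_history import DiseaseCourse, stage_at
from .params import ParticipationParams, TestCharacteristics
from .population import IndividualProfile

DESIGNS = ("S", "T", "B", "A")
AGE_WINDOWS = ((55, 80), (60, 80), (55, 75), (60, 75))
RISK_THRESHOLDS = (3.0, 4.0, 5.0)
STOP_AGE = 80.0  # screens in A/B stop strictly before the 80th birthday

TRUE_POSITIVE = "true_positive"
FALSE_NEGATIVE = "false_negative"
FALSE_POSITIVE = "false_positive_or_indeterminate"
TRUE_NEGATIVE = "true_negative"


@dataclass(frozen=True)
class StrategySpec:
    """One screening policy: design x entry-age window x risk threshold."""

    design: str                    # "S" | "T" | "B" | "A" | "none"
    age_min: int = 55
    age_max: int = 80
    risk_threshold_percent: float = 3.0

    def __post_init__(self):
        if self.design not in DESIGNS + ("none",):
            raise ValueError(f"unknown design {self.design!r}")

    @property
    def name(self) -> str:
        if self.design == "none":
            return "no-screening"
        return (f"{self.design}-{self.age_min}-{self.age_max}"
                f"-{self.risk_threshold_percent:g}%")


NO_SCREENING = StrategySpec(design="none")


def full_strategy_grid() -> list[StrategySpec]:
    """The 48 intervention strategies (4 designs x 4 windows x 3 thresholds)."""
    return [StrategySpec(design=d, age_min=lo, age_max=hi, risk_threshold_percent=thr)
            for d in DESIGNS for (lo, hi) in AGE_WINDOWS for thr in RISK_THRESHOLDS]


def build_schedule(design: str, entry_age: float) -> list[float]:
    """Screen times in years from entry.

    S has exactly one screen at entry; T exactly three (0, 1, 2 years,
    uncapped per protocol); A/B repeat annually/biennially while the attained
    age stays strictly below the 80th birthday.
    """
    if design == "none":
        return []
    if design == "S":
        return [0.0]
    if design == "T":
        return [0.0, 1.0, 2.0]
    step = {"A": 1.0, "B": 2.0}[design]
    times, t = [], 0.0
    while entry_age + t < STOP_AGE:
        times.append(t)
        t += step
    return times


def check_eligibility(profile: IndividualProfile, spec: StrategySpec) -> bool:
    """Entry age within the window (inclusive, by completed years) and
    predicted risk at or above the threshold (>= per protocol wording)."""
    if spec.design == "none":
        return False
    age = math.floor(profile.entry_age)
    if not (spec.age_min <= age <= spec.age_max):
        return False
    return profile.risk_percent >= spec.risk_threshold_percent


def sample_participation(profile: IndividualProfile, p: ParticipationParams,
                         u: tuple[float, float] | None = None) -> dict[str, bool]:
    """Invite response and programme joining, Bernoulli per published uptake.

    Non-joiners are retained in the invited population and receive no
    screening (control pathway)."""
    if u is None:
        rng = profile.rng("participation")
        u = (float(rng.random()), float(rng.random()))
    responds = u[0] < p.p_response
    joins = responds and (u[1] < p.p_join_given_eligible)
    return {"responds": responds, "joins": joins}


@dataclass
class ScreenEvent:
    time: float   # years from entry
    result: str


@dataclass
class DiagnosisRecord:
    time: float          # years from entry
    stage: int           # ladder index at diagnosis
    mode: str            # "screen_detected" | "clinical" | "interval"


def apply_ldct(has_occult: bool, test: TestCharacteristics, u: float) -> str:
    """Binary test gate: one uniform draw against sensitivity/specificity."""
    if has_occult:
        return TRUE_POSITIVE if u < test.sensitivity else FALSE_NEGATIVE
    return FALSE_POSITIVE if u >= test.specificity else TRUE_NEGATIVE


def run_screening_pathway(profile: IndividualProfile, course: DiseaseCourse | None,
                          schedule: Sequence[float], test: TestCharacteristics,
                          test_uniforms: Sequence[float],
                          oc_death_time: float) -> tuple[list[ScreenEvent],
                                                         DiagnosisRecord | None]:
    """Walk the scheduled screens in time order over the latent course.

    The pathway ends at the first true positive (immediate diagnosis at the
    occupied stage), at clinical presentation (mode "interval" when it falls
    between two scheduled screens of the joined programme, "clinical" when it
    precedes the first or follows the last screen), or at other-cause death.
    False negatives stay in the programme.  Times are years from entry.
    """
    events: list[ScreenEvent] = []
    entry_age = profile.entry_age
    presentation_t = (course.presentation_age - entry_age) if course is not None else INF_T
    attended = 0
    for k, t in enumerate(schedule):
        if t >= oc_death_time:
            break
        if presentation_t <= t:
            return events, _presentation_record(course, entry_age, schedule,
                                                attended, oc_death_time)
        occupied = stage_at(entry_age + t, course)
        has_occult = occupied is not None
        result = apply_ldct(has_occult, test, float(test_uniforms[k]))
        events.append(ScreenEvent(time=t, result=result))
        attended += 1
        if result == TRUE_POSITIVE:
            return events, DiagnosisRecord(time=t, stage=occupied, mode="screen_detected")
    if presentation_t < oc_death_time:
        return events, _presentation_record(course, entry_age, schedule,
                                            attended, oc_death_time)
    return events, None


INF_T = float("inf")


def _presentation_record(course: DiseaseCourse, entry_age: float,
                         schedule: Sequence[float], attended: int,
                         oc_death_time: float) -> DiagnosisRecord | None:
    t = course.presentation_age - entry_age
    if t >= oc_death_time:
        return None
    later_screens = any(s >= t and s < oc_death_time for s in schedule[attended:])
    mode = "interval" if (attended >= 1 and later_screens) else "clinical"
    return DiagnosisRecord(time=t, stage=course.presentation_stage, mode=mode)


def screen_test_uniforms(profile: IndividualProfile, n: int) -> np.ndarray:
    """Per-screen test uniforms from the person's dedicated substream (CRN:
    identical across strategies, consumed in schedule order)."""
    return profile.rng("screen").random(n)
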