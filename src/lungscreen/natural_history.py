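"""Latent disease natural history.

Age at preclinical onset is lognormal; onset ages beyond the lifetime horizon
(closing age 100) count as no lifetime onset.  From onset the tumour occupies
stage IA and, in each occupied stage, two independent exponential clocks
compete: progression to the next stage (absent in stage IV) and clinical
presentation at the current stage.  The earlier clock fires; the realised
course records every stage-entry age and the presentation age/stage.  Death
from occult (undiagnosed) disease is impossible — mortality from preclinical
lung cancer is assumed negligible — so the course is independent of the
other-cause death time and can be sampled once and shared across strategy
arms.

In the base case all simulants share the same rates; the heterogeneity
scenario multiplies each individual's progression and presentation rates by a
unit-mean gamma frailty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import NaturalHistoryParams
from .stages import N_STAGES, STAGES

LIFETIME_CLOSING_AGE = 100.0
INF = float("inf")


@dataclass
class DiseaseCourse:
    """One simulant's latent tumour timeline, in absolute age (years).

    ``stage_entry_age[s]`` is +inf for stages never reached.  ``onset_age``
    equals ``stage_entry_age[0]``.  ``presentation_age`` is +inf when the
    tumour never presents clinically; otherwise ``presentation_stage`` is the
    occupied stage at presentation.
    """

    onset_age: float
    stage_entry_age: np.ndarray          # shape (7,), non-decreasing, +inf tail
    presentation_age: float
    presentation_stage: int | None       # ladder index, None if never presents


def sample_onset_age(p: NaturalHistoryParams, rng: np.random.Generator) -> float:
    """Lognormal age at preclinical onset; > closing age counts as no onset."""
    age = math.exp(p.onset_lognormal_mu + p.onset_lognormal_sigma * rng.standard_normal())
    return age if age <= LIFETIME_CLOSING_AGE else INF


def sample_disease_course(onset_age: float, p: NaturalHistoryParams,
                          rng: np.random.Generator,
                          frailty: float = 1.0) -> DiseaseCourse:
    """Run the competing progression/presentation clocks from a finite onset."""
    if not math.isfinite(onset_age):
        raise ValueError("onset must be finite to sample a disease course")
    entry = np.full(N_STAGES, INF)
    entry[0] = onset_age
    t = onset_age
    presentation_age, presentation_stage = INF, None
    for s in range(N_STAGES):
        rate_prog = p.progression_rate[s] * frailty if s < N_STAGES - 1 else 0.0
        rate_pres = p.presentation_rate[s] * frailty
        t_prog = rng.exponential(1.0 / rate_prog) if rate_prog > 0 else INF
        t_pres = rng.exponential(1.0 / rate_pres) if rate_pres > 0 else INF
        if t_pres <= t_prog:
            if math.isfinite(t_pres):
                presentation_age, presentation_stage = t + t_pres, s
            break
        t = t + t_prog
        entry[s + 1] = t
    return DiseaseCourse(onset_age=onset_age, stage_entry_age=entry,
                         presentation_age=presentation_age,
                         presentation_stage=presentation_stage)


def stage_at(age: float, course: DiseaseCourse | None) -> int | None:
    """Occupied ladder index at ``age`` (entry boundary inclusive); None before
    onset or with no course."""
    if course is None or age < course.onset_age:
        return None
    return int(np.searchsorted(course.stage_entry_age, age, side="right")) - 1


def sample_course_for_profile(entry_age: float, p: NaturalHistoryParams,
                              rng: np.random.Generator,
                              frailty: float = 1.0,
                              max_tries: int = 1000) -> DiseaseCourse | None:
    """Course for a simulant entering without a clinical diagnosis.

    Onset age is sampled unconditionally (which makes prevalent occult disease
    at entry internally consistent with subsequent incidence); courses whose
    clinical presentation precedes entry describe people already diagnosed,
    who cannot enter, so the whole course is redrawn.  Returns None when no
    lifetime onset occurs.
    """
    for _ in range(max_tries):
        onset = sample_onset_age(p, rng)
        if not math.isfinite(onset):
            return None
        course = sample_disease_course(onset, p, rng, frailty=frailty)
        if course.presentation_age >= entry_age:
            return course
    raise RuntimeError("rejection sampling failed: presentation always precedes entry")


def course_event_log(person_id: int, course: DiseaseCourse | None) -> list[dict]:
    """Flat event log (id, event, age, stage) for debugging and oracle tests."""
    if course is None:
        return []
    events = [{"id": person_id, "event": "stage_entry", "age": float(a), "stage": STAGES[s]}
              for s, a in enumerate(course.stage_entry_age) if math.isfinite(a)]
    if course.presentation_stage is not None:
        events.append({"id": person_id, "event": "presentation",
                       "age": float(course.presentation_age),
                       "stage": STAGES[course.presentation_stage]})
    return events
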