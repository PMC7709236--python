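"""Discounted lifetime costs and QALYs per simulant and arm.

Utility flows are discounted continuously at the annual rate (factor
(1+r)^(-t)); point costs are discounted at their event time.  The utility
path is the sex/age-band baseline until diagnosis, then the broad-stage
utility (stage I keeps baseline, with age-band steps) constant until death.
Screen attendance and false-positive results subtract small rectangular
disutility decrements.  Costs comprise programme administration, LDCT scans,
false-positive workup, stage-matched care flows for at most two years
post-diagnosis (year two adjusted, truncated at death) and an end-of-life
cost at lung-cancer deaths only; a false-negative screen incurs no care cost
until a true diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import CostParams, UtilityParams
from .population import IndividualProfile
from .screening import FALSE_POSITIVE
from .stages import BROAD_STAGE, STAGES
from .survival import PersonOutcome

#: Table-style cost categories the population totals decompose into
COST_CATEGORIES = ("screening_administration", "ldct_screening",
                   "lung_cancer_care", "end_of_life")


def discount_factor(t: float, r: float) -> float:
    """Present-value factor (1+r)^(-t), continuous in t; 1 everywhere at r=0."""
    if t < 0:
        raise ValueError("time must be >= 0")
    return (1.0 + r) ** (-t)


def discounted_flow(value: float, t_start: float, t_end: float, r: float) -> float:
    """Closed-form integral of a constant flow over [t_start, t_end]:
    value * ((1+r)^-t1 - (1+r)^-t2) / ln(1+r); reduces to value*(t2-t1) at r=0."""
    if t_end <= t_start:
        return 0.0
    if r == 0.0:
        return value * (t_end - t_start)
    log1pr = math.log1p(r)
    return value * (discount_factor(t_start, r) - discount_factor(t_end, r)) / log1pr


def accrue_qalys(outcome: PersonOutcome, profile: IndividualProfile,
                 u: UtilityParams, r: float) -> float:
    """Discounted QALYs from entry to death for one resolved outcome."""
    death = outcome.death_time
    dx = outcome.diagnosis
    dx_time = dx.time if dx is not None else death

    total = 0.0
    # baseline (age-banded) utility up to diagnosis or death
    total += _banded_baseline(profile, u, 0.0, min(dx_time, death), r)
    # post-diagnosis utility until death
    if dx is not None and dx_time < death:
        broad = BROAD_STAGE[STAGES[dx.stage]]
        if broad == "I":
            total += _banded_baseline(profile, u, dx_time, death, r)
        else:
            util = u.stage_utility(broad, profile.sex, profile.entry_age + dx_time)
            total += discounted_flow(util, dx_time, death, r)
    # rectangular disutility decrements, truncated at death
    for ev in outcome.screens:
        total -= discounted_flow(u.disutility_screen, ev.time,
                                 min(ev.time + u.disutility_screen_duration_years, death), r)
        if ev.result == FALSE_POSITIVE:
            total -= discounted_flow(u.disutility_fp, ev.time,
                                     min(ev.time + u.disutility_fp_duration_years, death), r)
    return total


def _banded_baseline(profile: IndividualProfile, u: UtilityParams,
                     t0: float, t1: float, r: float) -> float:
    """Baseline utility flow with steps at age-band crossings."""
    if t1 <= t0:
        return 0.0
    entry = profile.entry_age
    cuts = sorted({t0, t1, *(e - entry for e in u.age_band_edges if t0 < e - entry < t1)})
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        total += discounted_flow(u.baseline(profile.sex, entry + a), a, b, r)
    return total


@dataclass
class CostBreakdown:
    screening_administration: float = 0.0
    ldct_screening: float = 0.0
    lung_cancer_care: float = 0.0     # stage-matched care + FP workup
    end_of_life: float = 0.0

    @property
    def total(self) -> float:
        return (self.screening_administration + self.ldct_screening +
                self.lung_cancer_care + self.end_of_life)


def accrue_costs(outcome: PersonOutcome, c: CostParams, r: float,
                 invited: bool = False, responded: bool = False,
                 joined: bool = False) -> CostBreakdown:
    """Discounted lifetime cost components for one resolved outcome.

    Administration is charged at entry: the invite cost to every invitee,
    questionnaire scoring to responders, the follow-up invite to joiners.
    """
    b = CostBreakdown()
    if invited:
        b.screening_administration += c.invite
    if responded:
        b.screening_administration += c.questionnaire_scoring
    if joined:
        b.screening_administration += c.followup_invite

    for ev in outcome.screens:
        df = discount_factor(ev.time, r)
        b.ldct_screening += c.ldct_scan * df
        if ev.result == FALSE_POSITIVE:
            b.lung_cancer_care += c.fp_workup * df

    dx = outcome.diagnosis
    if dx is not None and dx.time < outcome.death_time:
        year1 = c.care_year1[dx.stage]
        death = outcome.death_time
        b.lung_cancer_care += discounted_flow(year1, dx.time, min(dx.time + 1.0, death), r)
        b.lung_cancer_care += discounted_flow(year1 * c.care_year2_factor,
                                              dx.time + 1.0, min(dx.time + 2.0, death), r)
    if outcome.death_cause == "lung_cancer":
        b.end_of_life += c.end_of_life * discount_factor(outcome.death_time, r)
    return b
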