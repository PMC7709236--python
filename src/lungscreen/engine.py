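"""Strategy engine: run screening strategies over a shared CRN pool.

The pool's latent state (disease course, other-cause death, participation
and test uniforms, the common survival quantile) is sampled once per seed and
shared by every strategy arm, so strategy contrasts are common-random-number
paired: the no-screening counterfactual of each simulant is fixed, and
differences between strategies reflect the intervention alone.

``run_strategy`` routes every pool member through eligibility, participation,
the screening pathway, death resolution and the economics, and aggregates
primary (cost/QALY, two denominators) and secondary epidemiological
outcomes.  ``compute_frontier`` applies standard dominance and extended-
dominance pruning; ``optimise_population`` grid-searches net monetary
benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import economics
from .economics import CostBreakdown
from .natural_history import DiseaseCourse, sample_course_for_profile
from .params import ModelParameters
from .population import (IndividualProfile, LifeTable, assign_risk_score,
                         generate_pool, person_rng)
from .screening import (FALSE_POSITIVE, NO_SCREENING, StrategySpec, build_schedule,
                        check_eligibility, run_screening_pathway)
from .stages import is_early
from .survival import PersonOutcome, resolve_death

MAX_SCREENS = 26  # annual screening from age 55 needs at most 25 screens


# ---------------------------------------------------------------------------
# pool state shared across strategies
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPerson:
    profile: IndividualProfile
    course: DiseaseCourse | None
    oc_death_time: float            # years from entry
    participation_u: tuple[float, float]
    screen_uniforms: np.ndarray     # (MAX_SCREENS,)
    survival_quantile: float
    control_outcome: PersonOutcome = None  # type: ignore[assignment]
    control_qalys: float = 0.0
    control_costs: CostBreakdown = field(default_factory=CostBreakdown)


@dataclass
class SimulatedPool:
    params: ModelParameters
    seed: int
    people: list[SimulatedPerson]

    @property
    def n(self) -> int:
        return len(self.people)


def _master(seed: int, tag: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0xB0, tag))))


def build_pool(params: ModelParameters, seed: int, n: int | None = None) -> SimulatedPool:
    """Simulate the shared pool state for ``n`` simulants (default pool_size)."""
    n = params.pool_size if n is None else n
    profiles = generate_pool(n, params.demographics, seed)
    table = LifeTable.from_params(params)
    table.check_coverage(params.demographics.age_min)

    oc_u = _master(seed, 1).random(n)
    risk_z = _master(seed, 2).standard_normal(n)
    part_u = _master(seed, 3).random((n, 2))
    surv_u = _master(seed, 4).random(n)
    screen_u = _master(seed, 5).random((n, MAX_SCREENS))
    nh = params.natural_history
    if nh.heterogeneity and nh.frailty_variance > 0:
        v = nh.frailty_variance
        frailty = _master(seed, 6).gamma(shape=1.0 / v, scale=v, size=n)
    else:
        frailty = np.ones(n)

    oc_times = _vector_oc_death(profiles, table, oc_u)

    people: list[SimulatedPerson] = []
    r = params.discount_rate_annual
    for i, prof in enumerate(profiles):
        course = sample_course_for_profile(prof.entry_age, nh,
                                           prof.rng("disease"), frailty=float(frailty[i]))
        prof.risk_percent = assign_risk_score(prof, course, params.risk_model,
                                              z=float(risk_z[i]))
        person = SimulatedPerson(profile=prof, course=course,
                                 oc_death_time=float(oc_times[i]),
                                 participation_u=(float(part_u[i, 0]), float(part_u[i, 1])),
                                 screen_uniforms=screen_u[i],
                                 survival_quantile=float(np.clip(surv_u[i], 1e-12, 1 - 1e-12)))
        dx_c = _control_diagnosis(person)
        _, out_c = resolve_death(None, dx_c, person.oc_death_time,
                                 params.survival, person.survival_quantile)
        person.control_outcome = out_c
        person.control_qalys = economics.accrue_qalys(out_c, prof, params.utilities, r)
        person.control_costs = economics.accrue_costs(out_c, params.costs, r)
        people.append(person)
    return SimulatedPool(params=params, seed=seed, people=people)


def _vector_oc_death(profiles: list[IndividualProfile], table: LifeTable,
                     u: np.ndarray) -> np.ndarray:
    """Vectorised piecewise-exponential inverse-CDF draw per person."""
    out = np.empty(len(profiles))
    entry = np.array([p.entry_age for p in profiles])
    e = -np.log1p(-np.clip(u, 0.0, 1.0 - 1e-300))
    keys = np.array([f"{p.sex}|{p.smoking_category}" for p in profiles])
    for key in np.unique(keys):
        sex, smoking = key.split("|")
        grid, cum = table._cum_hazard(sex, smoking)
        mask = keys == key
        h0 = np.interp(entry[mask], grid, cum)
        target = h0 + e[mask]
        death_age = np.where(target >= cum[-1], table.closing_age,
                             np.interp(target, cum, grid))
        out[mask] = np.minimum(death_age, table.closing_age) - entry[mask]
    return out


def _control_diagnosis(person: SimulatedPerson):
    from .screening import DiagnosisRecord

    course = person.course
    if course is None or course.presentation_stage is None:
        return None
    t = course.presentation_age - person.profile.entry_age
    if t >= person.oc_death_time:
        return None
    return DiagnosisRecord(time=t, stage=course.presentation_stage, mode="clinical")


# ---------------------------------------------------------------------------
# strategy results
# ---------------------------------------------------------------------------

@dataclass
class StrategyResult:
    strategy: str
    n_pool: int
    n_invited: int
    n_participants: int
    # invited-population denominator (per invitee, incl. non-participants)
    mean_cost_invited: float = math.nan
    mean_qaly_invited: float = math.nan
    inc_cost_invited: float = 0.0
    inc_qaly_invited: float = 0.0
    se_inc_cost_invited: float = 0.0
    se_inc_qaly_invited: float = 0.0
    icer_vs_none: float | None = None
    # mixture-identity components (strategy arm, invited denominator)
    mean_cost_participants_arm: float | None = None
    mean_cost_nonparticipants_arm: float | None = None
    mean_qaly_participants_arm: float | None = None
    mean_qaly_nonparticipants_arm: float | None = None
    # participant denominator
    inc_cost_participant: float | None = None
    inc_qaly_participant: float | None = None
    screens_per_participant: float | None = None
    fp_per_participant: float | None = None
    mean_lead_time: float | None = None
    life_years_gained_participant: float | None = None
    diagnoses_per_100k: float | None = None
    diagnoses_per_100k_control: float | None = None
    lc_deaths_per_100k: float | None = None
    lc_deaths_per_100k_control: float | None = None
    interval_cancer_share: float | None = None
    screen_detected_share: float | None = None
    or_early_diagnosis: float | None = None
    rr_diagnosis: float | None = None
    five_year_survival: float | None = None
    five_year_survival_control: float | None = None
    mortality_reduction: float | None = None
    mean_age_shift_diagnosis: float | None = None
    mean_age_shift_death: float | None = None
    mean_age_shift_lc_death: float | None = None
    cost_categories: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def run_strategy(pool: SimulatedPool, spec: StrategySpec,
                 collect_outcomes: bool = False) -> StrategyResult:
    """Evaluate one strategy (or the no-screening comparator) over the pool.

    The invited population is every pool member passing the eligibility
    filter (for no-screening: the whole pool, with nobody screened); the
    no-screening counterfactual of the same people is the CRN-paired control.
    """
    params = pool.params
    r = params.discount_rate_annual

    outcomes_s: list[PersonOutcome] = []
    outcomes_c: list[PersonOutcome] = []
    persons: list[SimulatedPerson] = []
    costs_s, qalys_s, costs_c, qalys_c = [], [], [], []
    joined_flags: list[bool] = []
    categories = {k: 0.0 for k in economics.COST_CATEGORIES}

    for person in pool.people:
        if spec.design == "none":
            invited = True
        else:
            invited = check_eligibility(person.profile, spec)
        if not invited:
            continue
        persons.append(person)

        responds = joins = False
        if spec.design != "none":
            from .screening import sample_participation

            part = sample_participation(person.profile, params.participation,
                                        u=person.participation_u)
            responds, joins = part["responds"], part["joins"]

        if joins:
            schedule = build_schedule(spec.design, person.profile.entry_age)
            events, dx_s = run_screening_pathway(
                person.profile, person.course, schedule, params.test,
                person.screen_uniforms, person.oc_death_time)
            dx_c = person.control_outcome.diagnosis
            out_s, out_c = resolve_death(dx_s, dx_c, person.oc_death_time,
                                         params.survival, person.survival_quantile)
            out_s.screens = events
            q_s = economics.accrue_qalys(out_s, person.profile, params.utilities, r)
            c_s = economics.accrue_costs(out_s, params.costs, r,
                                         invited=True, responded=True, joined=True)
        else:
            out_s = person.control_outcome
            out_c = person.control_outcome
            q_s = person.control_qalys
            c_s = CostBreakdown(**vars(person.control_costs))
            if spec.design != "none":
                c_s.screening_administration += params.costs.invite
                if responds:
                    c_s.screening_administration += params.costs.questionnaire_scoring

        outcomes_s.append(out_s)
        outcomes_c.append(out_c)
        joined_flags.append(joins)
        qalys_s.append(q_s)
        costs_s.append(c_s.total)
        qalys_c.append(person.control_qalys)
        costs_c.append(person.control_costs.total)
        for k in categories:
            categories[k] += getattr(c_s, k)

    res = StrategyResult(strategy=spec.name, n_pool=pool.n,
                         n_invited=len(persons), n_participants=sum(joined_flags))
    if not persons:
        return res

    cs, qs = np.asarray(costs_s), np.asarray(qalys_s)
    cc, qc = np.asarray(costs_c), np.asarray(qalys_c)
    res.mean_cost_invited = float(cs.mean())
    res.mean_qaly_invited = float(qs.mean())
    res.inc_cost_invited = float((cs - cc).mean())
    res.inc_qaly_invited = float((qs - qc).mean())
    n_inv = len(persons)
    res.se_inc_cost_invited = float((cs - cc).std(ddof=1) / math.sqrt(n_inv)) if n_inv > 1 else 0.0
    res.se_inc_qaly_invited = float((qs - qc).std(ddof=1) / math.sqrt(n_inv)) if n_inv > 1 else 0.0
    if res.inc_qaly_invited != 0.0:
        res.icer_vs_none = res.inc_cost_invited / res.inc_qaly_invited
    res.cost_categories = categories

    joined = np.asarray(joined_flags)
    if joined.any():
        res.mean_cost_participants_arm = float(cs[joined].mean())
        res.mean_qaly_participants_arm = float(qs[joined].mean())
    if (~joined).any():
        res.mean_cost_nonparticipants_arm = float(cs[~joined].mean())
        res.mean_qaly_nonparticipants_arm = float(qs[~joined].mean())

    if spec.design == "none":
        # comparator: participant metrics defined on the whole pool, no screening
        sec = secondary_outcomes(outcomes_s, outcomes_c,
                                 [p.profile for p in persons])
        _apply_secondary(res, sec)
        res.screens_per_participant = 0.0
        res.fp_per_participant = 0.0
        return res

    if joined.any():
        part_out_s = [o for o, j in zip(outcomes_s, joined_flags) if j]
        part_out_c = [o for o, j in zip(outcomes_c, joined_flags) if j]
        part_prof = [p.profile for p, j in zip(persons, joined_flags) if j]
        res.inc_cost_participant = float((cs[joined] - cc[joined]).mean())
        res.inc_qaly_participant = float((qs[joined] - qc[joined]).mean())
        sec = secondary_outcomes(part_out_s, part_out_c, part_prof)
        _apply_secondary(res, sec)
    return res


def paired_outcome_table(pool: SimulatedPool, spec: StrategySpec):
    """Per-person paired (screening vs control) history table, one row per
    arm: id, arm, dx mode/stage/time, death time, cause, lead time,
    over-diagnosis flag.  Intended for debugging and oracle tests."""
    import pandas as pd

    from .screening import build_schedule, run_screening_pathway
    from .stages import STAGES

    rows = []
    for person in pool.people:
        schedule = build_schedule(spec.design, person.profile.entry_age)
        _, dx_s = run_screening_pathway(person.profile, person.course, schedule,
                                        pool.params.test, person.screen_uniforms,
                                        person.oc_death_time)
        out_s, out_c = resolve_death(dx_s, person.control_outcome.diagnosis,
                                     person.oc_death_time, pool.params.survival,
                                     person.survival_quantile)
        for out in (out_s, out_c):
            dx = out.diagnosis
            rows.append({
                "id": person.profile.id, "arm": out.arm,
                "dx_mode": dx.mode if dx else None,
                "dx_stage": STAGES[dx.stage] if dx else None,
                "dx_time": dx.time if dx else None,
                "death_time": out.death_time, "cause": out.death_cause,
                "lead_time": out.lead_time, "overdiagnosed": out.overdiagnosed,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# secondary epidemiological outcomes
# ---------------------------------------------------------------------------

def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> float:
    """(a*d)/(b*c) with the Haldane-Anscombe 0.5 correction on any zero cell."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def secondary_outcomes(outcomes_s: Sequence[PersonOutcome],
                       outcomes_c: Sequence[PersonOutcome],
                       profiles: Sequence[IndividualProfile]) -> dict:
    """Secondary metric block over CRN-paired participant outcomes."""
    n = len(outcomes_s)
    if n == 0:
        return {}
    dx_s = [o.diagnosis for o in outcomes_s]
    dx_c = [o.diagnosis for o in outcomes_c]
    n_dx_s = sum(d is not None for d in dx_s)
    n_dx_c = sum(d is not None for d in dx_c)
    lc_s = sum(o.death_cause == "lung_cancer" for o in outcomes_s)
    lc_c = sum(o.death_cause == "lung_cancer" for o in outcomes_c)

    early_s = sum(1 for d in dx_s if d is not None and is_early(d.stage))
    late_s = n_dx_s - early_s
    early_c = sum(1 for d in dx_c if d is not None and is_early(d.stage))
    late_c = n_dx_c - early_c

    screens = [len(o.screens) for o in outcomes_s]
    fps = [sum(ev.result == FALSE_POSITIVE for ev in o.screens) for o in outcomes_s]
    leads = [o.lead_time for o in outcomes_s if o.lead_time is not None]
    lys = [o.death_time - c.death_time for o, c in zip(outcomes_s, outcomes_c)]

    def _surv5(outs):
        dx = [(o.death_time - o.diagnosis.time) for o in outs if o.diagnosis is not None]
        return sum(t > 5.0 for t in dx) / len(dx) if dx else None

    modes = [d.mode for d in dx_s if d is not None]
    sec = {
        "screens_per_participant": float(np.mean(screens)),
        "fp_per_participant": float(np.mean(fps)),
        "mean_lead_time": float(np.mean(leads)) if leads else None,
        "life_years_gained_participant": float(np.mean(lys)),
        "diagnoses_per_100k": 1e5 * n_dx_s / n,
        "diagnoses_per_100k_control": 1e5 * n_dx_c / n,
        "lc_deaths_per_100k": 1e5 * lc_s / n,
        "lc_deaths_per_100k_control": 1e5 * lc_c / n,
        "interval_cancer_share": (modes.count("interval") / n_dx_s) if n_dx_s else None,
        "screen_detected_share": (modes.count("screen_detected") / n_dx_s) if n_dx_s else None,
        "or_early_diagnosis": odds_ratio_2x2(early_s, late_s, early_c, late_c)
        if (n_dx_s and n_dx_c) else None,
        "rr_diagnosis": (n_dx_s / n_dx_c) if n_dx_c else None,
        "five_year_survival": _surv5(outcomes_s),
        "five_year_survival_control": _surv5(outcomes_c),
        "mortality_reduction": (1.0 - lc_s / lc_c) if lc_c else None,
    }

    def _mean_age(outs, profs, what):
        vals = []
        for o, p in zip(outs, profs):
            if what == "dx" and o.diagnosis is not None:
                vals.append(p.entry_age + o.diagnosis.time)
            elif what == "death":
                vals.append(p.entry_age + o.death_time)
            elif what == "lc_death" and o.death_cause == "lung_cancer":
                vals.append(p.entry_age + o.death_time)
        return float(np.mean(vals)) if vals else None

    for what, key in (("dx", "mean_age_shift_diagnosis"),
                      ("death", "mean_age_shift_death"),
                      ("lc_death", "mean_age_shift_lc_death")):
        a_s = _mean_age(outcomes_s, profiles, what)
        a_c = _mean_age(outcomes_c, profiles, what)
        sec[key] = (a_s - a_c) if (a_s is not None and a_c is not None) else None
    return sec


def _apply_secondary(res: StrategyResult, sec: dict) -> None:
    for key, value in sec.items():
        setattr(res, key, value)


# ---------------------------------------------------------------------------
# grid, frontier and optimisation
# ---------------------------------------------------------------------------

def run_grid(pool: SimulatedPool, specs: Sequence[StrategySpec] | None = None,
             include_comparator: bool = True) -> list[StrategyResult]:
    from .screening import full_strategy_grid

    specs = list(specs) if specs is not None else full_strategy_grid()
    results = []
    if include_comparator:
        results.append(run_strategy(pool, NO_SCREENING))
    results.extend(run_strategy(pool, s) for s in specs)
    return results


@dataclass
class FrontierEntry:
    strategy: str
    inc_cost: float
    inc_qaly: float
    icer_vs_none: float | None
    icer_vs_previous: float | None


def compute_frontier(results: Sequence[StrategyResult]) -> list[FrontierEntry]:
    """Cost-effectiveness frontier on per-invitee incrementals vs no screening.

    Strategies strictly dominated (costlier, no more effective) or extendedly
    dominated (never NMB-optimal at any threshold) are excluded; the greedy
    minimum-ICER walk from the comparator yields entries whose ICER versus
    the previous frontier strategy increases along increasing QALY.
    """
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names in results")
    by_name = {r.strategy: (r.inc_qaly_invited, r.inc_cost_invited) for r in results}
    comparator = next((r.strategy for r in results if r.strategy == NO_SCREENING.name), None)
    if comparator is None:
        raise ValueError("results must include the no-screening comparator")

    frontier: list[FrontierEntry] = []
    cur_q, cur_c = by_name[comparator]
    remaining = {n: qc for n, qc in by_name.items() if n != comparator}
    while True:
        best_name, best_icer = None, math.inf
        for name, (q, c) in remaining.items():
            if q <= cur_q:
                continue  # no more effective than the current frontier point
            icer = (c - cur_c) / (q - cur_q)
            better = icer < best_icer - 1e-12
            tie_more_qaly = (abs(icer - best_icer) <= 1e-12 and best_name is not None
                             and q > by_name[best_name][0])
            if better or tie_more_qaly:
                best_name, best_icer = name, icer
        if best_name is None:
            break
        q, c = by_name[best_name]
        q0, c0 = by_name[comparator]
        icer_none = (c - c0) / (q - q0) if q != q0 else None
        frontier.append(FrontierEntry(strategy=best_name, inc_cost=c, inc_qaly=q,
                                      icer_vs_none=icer_none,
                                      icer_vs_previous=best_icer))
        cur_q, cur_c = q, c
        del remaining[best_name]
    return frontier


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """Mean NMB per invitee versus no screening: wtp * dQALY - dCost."""
    return wtp * result.inc_qaly_invited - result.inc_cost_invited


def optimise_population(pool: SimulatedPool, design: str,
                        age_windows: Sequence[tuple[int, int]],
                        thresholds: Sequence[float],
                        wtp: float) -> tuple[StrategySpec, float | None, float]:
    """Exhaustive NMB grid search over age windows x risk thresholds.

    Returns (best spec, its ICER vs no screening, its NMB).  No screening
    (NMB 0) is always a candidate; ties break toward narrower age windows.
    """
    if not age_windows or not thresholds:
        raise ValueError("grids must be nonempty")
    best: tuple[float, float, StrategySpec, float | None] | None = None
    for lo, hi in age_windows:
        for thr in thresholds:
            spec = StrategySpec(design=design, age_min=lo, age_max=hi,
                                risk_threshold_percent=thr)
            res = run_strategy(pool, spec)
            nmb = net_monetary_benefit(res, wtp)
            width = float(hi - lo)
            key = (nmb, -width)
            if best is None or key > (best[0], -best[1]):
                best = (nmb, width, spec, res.icer_vs_none)
    assert best is not None
    if best[0] <= 0.0:
        return NO_SCREENING, None, 0.0
    return best[2], best[3], best[0]
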