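"""Simulant pool generation and other-cause mortality.

The pool of heterogeneous simulants (age, sex, smoking category, predicted
risk) is shared across all screening strategies; every source of per-person
randomness is drawn from a named substream keyed on (master seed, person id,
stream name), so strategy arms are common-random-number (CRN) paired: the
same individual experiences identical latent disease, other-cause death and
participation draws under every strategy.

Other-cause death times are sampled from a piecewise-constant-hazard survival
distribution built from a per-age, per-sex life table: the all-cause rate is
multiplied by a smoking adjustment factor and the lung-cancer-specific rate
is subtracted (floored at zero), because lung-cancer death is modelled
explicitly and must not be double counted.  The table closes at a fixed age
with certain death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .natural_history import DiseaseCourse
from .params import DemographicParams, LifeTableRow, ModelParameters, RiskModelParams

# named substreams; codes keep the (seed, person, stream) key space disjoint
STREAM_CODES = {
    "disease": 1,      # onset age + stage clocks (variable number of draws)
    "oc_death": 2,
    "risk": 3,
    "participation": 4,
    "screen": 5,
    "survival": 6,
    "frailty": 7,
}


def person_rng(master_seed: int, person_id: int, stream: str) -> np.random.Generator:
    """Independent, reproducible generator for one person's named substream."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence((master_seed, person_id,
                                                 STREAM_CODES[stream]))))


@dataclass
class IndividualProfile:
    id: int
    sex: str                    # "male" | "female"
    entry_age: float            # years, in [55, 80]
    smoking_category: str       # "current" | "former"
    master_seed: int
    risk_percent: float = float("nan")

    def rng(self, stream: str) -> np.random.Generator:
        return person_rng(self.master_seed, self.id, stream)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Adjusted other-cause hazard by integer age, per sex and smoking category.

    The cumulative hazard is piecewise linear (constant hazard within each
    one-year age interval), so sampling is exact inverse-CDF: draw E ~ Exp(1)
    and invert H(entry + t) - H(entry) = E.
    """

    ages: np.ndarray                       # integer ages, contiguous
    hazard: dict[tuple[str, str], np.ndarray]  # (sex, smoking) -> rate per age
    closing_age: float

    @classmethod
    def from_params(cls, params: ModelParameters) -> "LifeTable":
        return cls.from_rows(params.life_table,
                             smoking_factors={"current": params.smoking_factor_current,
                                              "former": params.smoking_factor_former},
                             closing_age=params.life_table_closing_age)

    @classmethod
    def from_rows(cls, rows: list[LifeTableRow], smoking_factors: dict[str, float],
                  closing_age: float = 100.0) -> "LifeTable":
        by_sex: dict[str, dict[int, LifeTableRow]] = {}
        for row in rows:
            by_sex.setdefault(row.sex, {})[row.age] = row
        ages = None
        hazard: dict[tuple[str, str], np.ndarray] = {}
        floored = False
        for sex, table in by_sex.items():
            a = np.array(sorted(table))
            if ages is None:
                ages = a
            for smoking, factor in smoking_factors.items():
                raw = np.array([table[age].all_cause_rate * factor
                                - table[age].lung_cancer_rate for age in a])
                if np.any(raw < 0):
                    floored = True
                hazard[(sex, smoking)] = np.maximum(raw, 0.0)
        if floored:
            warnings.warn("adjusted other-cause hazard floored at zero for some ages",
                          stacklevel=2)
        assert ages is not None
        return cls(ages=ages, hazard=hazard, closing_age=float(closing_age))

    def _cum_hazard(self, sex: str, smoking: str) -> tuple[np.ndarray, np.ndarray]:
        h = self.hazard[(sex, smoking)]
        grid = np.concatenate([self.ages.astype(float), [self.ages[-1] + 1.0]])
        cum = np.concatenate([[0.0], np.cumsum(h)])
        return grid, cum

    def check_coverage(self, entry_age: float) -> None:
        lo, hi = int(np.floor(entry_age)), int(self.closing_age) - 1
        present = set(self.ages.tolist())
        for age in range(lo, hi + 1):
            if age not in present:
                raise DataError(f"life table missing age {age}")
        if np.any(np.diff(self.ages) != 1):
            gap_at = int(self.ages[np.argmax(np.diff(self.ages) != 1)]) + 1
            raise DataError(f"life table missing age {gap_at}")


def other_cause_death_time(profile: IndividualProfile, table: LifeTable,
                           u: float | None = None) -> float:
    """Sample years from entry to other-cause death (exact inverse CDF).

    ``u`` may be supplied directly (a uniform draw) for CRN control; by
    default the person's ``oc_death`` substream is used.  The draw is bounded
    above by the table's closing age, where death is certain.
    """
    if table.closing_age <= profile.entry_age:
        return 0.0
    table.check_coverage(profile.entry_age)
    if u is None:
        u = float(profile.rng("oc_death").random())
    e = -np.log1p(-min(u, 1.0 - 1e-300))  # Exp(1) target cumulative hazard
    grid, cum = table._cum_hazard(profile.sex, profile.smoking_category)
    h0 = float(np.interp(profile.entry_age, grid, cum))
    target = h0 + e
    if target >= cum[-1]:
        return float(table.closing_age - profile.entry_age)
    # cum is non-decreasing; invert by interpolation over strictly increasing part
    death_age = float(np.interp(target, cum, grid))
    return min(death_age, table.closing_age) - profile.entry_age


# ---------------------------------------------------------------------------
# pool generation
# ---------------------------------------------------------------------------

def generate_pool(n: int, demographics: DemographicParams, seed: int) -> list[IndividualProfile]:
    """Generate ``n`` simulant profiles; bit-identical for identical ``seed``.

    Profile attributes are drawn from a dedicated pool stream; each profile
    carries the master seed so its named substreams can be opened lazily and
    identically in every strategy arm.
    """
    if n < 1:
        raise ValueError(f"pool size must be >= 1, got {n}")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0xA11))))
    ages = rng.uniform(demographics.age_min, demographics.age_max, size=n)
    male = rng.random(n) < demographics.p_male
    current = rng.random(n) < demographics.p_current_smoker
    return [IndividualProfile(id=i,
                              sex="male" if male[i] else "female",
                              entry_age=float(ages[i]),
                              smoking_category="current" if current[i] else "former",
                              master_seed=seed)
            for i in range(n)]


def risk_indicator(profile: IndividualProfile, course: DiseaseCourse | None,
                   horizon_years: float) -> bool:
    """True iff occult disease is present at entry or onset occurs within the
    short-term horizon — the latent quantity the questionnaire proxy tracks."""
    if course is None:
        return False
    return course.onset_age <= profile.entry_age + horizon_years


def assign_risk_score(profile: IndividualProfile, course: DiseaseCourse | None,
                      risk: RiskModelParams,
                      z: float | None = None) -> float:
    """Predicted lung-cancer risk (%) from the questionnaire proxy.

    The score is lognormal noise around a baseline median, shifted up by a
    fixed multiplier when the latent indicator (occult prevalence or onset
    within the horizon) holds, so thresholding the score enriches the invited
    population in true short-term risk.  ``noise_sigma = 0`` degenerates to a
    two-level deterministic score.
    """
    if z is None:
        z = float(profile.rng("risk").standard_normal())
    indicator = risk_indicator(profile, course, risk.horizon_years)
    log_median = np.log(risk.baseline_median_percent) + \
        (np.log(risk.high_risk_multiplier) if indicator else 0.0)
    return float(np.exp(log_median + risk.noise_sigma * z))
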