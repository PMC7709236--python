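"""Model parameter schema, file I/O, validation and the bundled fixture set.

The canonical on-disk format is a nested-key YAML document carrying a
``schema_version`` field.  A life table can additionally be imported from /
exported to CSV, and a validated set can be exported to JSON.  Values not
printed in the source evidence base (the natural-history rates, stage-wise
survival and care costs, the life table) are fixture placeholders chosen to
give plausible epidemiology; they are NOT a calibrated parameter set, and a
transcribed calibrated set can be dropped in through :func:`load_parameter_set`.

Extra, non-schema keys are rejected by name unless namespaced under the
``extensions`` mapping, which is preserved verbatim.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterFormatError
from .stages import N_STAGES, N_TRANSITIONS, STAGES

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# component dataclasses
# ---------------------------------------------------------------------------

@dataclass
class NaturalHistoryParams:
    """Latent disease process: lognormal age at preclinical onset, and one
    competing pair of exponential clocks (progression vs clinical
    presentation) per occupied stage."""

    onset_lognormal_mu: float       # mean of log(age at onset)
    onset_lognormal_sigma: float    # sd of log(age at onset), > 0
    progression_rate: list[float]   # /year, one per stage transition (6)
    presentation_rate: list[float]  # /year, one per stage (7)
    heterogeneity: bool = False     # scenario switch: gamma frailty on all rates
    frailty_variance: float = 0.0   # variance of the unit-mean gamma frailty


@dataclass
class TestCharacteristics:
    sensitivity: float
    specificity: float


@dataclass
class ParticipationParams:
    p_response: float            # responds to invite and returns questionnaire
    p_join_given_eligible: float  # joins the programme given eligible response


@dataclass
class UtilityParams:
    """Health-state utilities.

    Baseline utility (smoker without clinically diagnosed lung cancer,
    occult disease included) is stepped by sex and age band.  Diagnosed
    broad-stage I keeps the baseline utility; stages II-IV use constant
    stage utilities until death.  Screen attendance and false-positive
    results carry temporary rectangular disutilities.
    """

    age_band_edges: list[float]       # ascending band lower edges, e.g. [55, 65, 75, 85]
    baseline_male: list[float]        # one utility per band
    baseline_female: list[float]
    stage_II: float = 0.77
    stage_III: float = 0.77
    stage_IV: float = 0.76
    disutility_screen: float = 0.010
    disutility_screen_duration_years: float = 14.0 / 365.25   # 2 weeks
    disutility_fp: float = 0.063
    disutility_fp_duration_years: float = 0.25                # 3 months

    def baseline(self, sex: str, age: float) -> float:
        """Baseline utility for a smoker of given sex at a given age."""
        table = self.baseline_male if sex == "male" else self.baseline_female
        idx = 0
        for i, edge in enumerate(self.age_band_edges):
            if age >= edge:
                idx = i
        return table[idx]

    def stage_utility(self, broad_stage: str, sex: str, age: float) -> float:
        if broad_stage == "I":
            return self.baseline(sex, age)
        return {"II": self.stage_II, "III": self.stage_III, "IV": self.stage_IV}[broad_stage]


@dataclass
class CostParams:
    """NHS/PSS perspective costs (GBP, price-year metadata only; no inflation
    is computed).  Care costs run for at most two years post-diagnosis with
    the second year adjusted by ``care_year2_factor``; end-of-life cost is
    charged at lung-cancer deaths only."""

    invite: float                   # per invitee (admin)
    questionnaire_scoring: float    # per responder (admin)
    followup_invite: float          # per joiner (admin)
    ldct_scan: float                # per attended screen, incl. nurse assessment
    fp_workup: float                # per false-positive/indeterminate result
    care_year1: list[float]         # /year flow in year 1 post-dx, per stage (7)
    care_year2_factor: float        # multiplier applied to year-1 flow in year 2
    end_of_life: float              # point cost at lung-cancer death


@dataclass
class SurvivalParams:
    """Post-diagnosis survival distribution by stage at diagnosis.

    Only the exponential family is implemented for the bundled fixture; the
    field is explicit so a transcribed calibrated set can name another family.
    """

    family: str = "exponential"
    rate: list[float] = field(default_factory=list)  # /year, one per stage (7)


@dataclass
class DemographicParams:
    age_min: float = 55.0
    age_max: float = 80.0
    p_male: float = 0.5
    p_current_smoker: float = 0.5


@dataclass
class RiskModelParams:
    """Risk-questionnaire proxy: predicted risk (%) is lognormal noise around
    a baseline median, multiplied up when occult disease is present at entry
    or onset occurs within ``horizon_years`` of entry.  With
    ``noise_sigma = 0`` the score is a deterministic two-level function of
    that latent indicator."""

    baseline_median_percent: float = 2.0
    high_risk_multiplier: float = 3.0
    noise_sigma: float = 0.6
    horizon_years: float = 3.0


@dataclass
class LifeTableRow:
    age: int
    sex: str
    all_cause_rate: float   # /year all-cause mortality rate
    lung_cancer_rate: float  # /year lung-cancer mortality rate to subtract


@dataclass
class ModelParameters:
    schema_version: int
    natural_history: NaturalHistoryParams
    test: TestCharacteristics
    participation: ParticipationParams
    utilities: UtilityParams
    costs: CostParams
    survival: SurvivalParams
    demographics: DemographicParams
    risk_model: RiskModelParams
    life_table: list[LifeTableRow]
    smoking_factor_current: float = 1.35
    smoking_factor_former: float = 1.15
    life_table_closing_age: int = 100
    discount_rate_annual: float = 0.035
    pool_size: int = 20_000
    price_year: int = 2016
    currency: str = "GBP"
    population_smokers_55_80: float = 13_000_000.0
    extensions: dict[str, Any] = field(default_factory=dict)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["life_table"] = [dataclasses.asdict(r) if not isinstance(r, dict) else r
                           for r in d["life_table"]]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        return _build(cls, dict(d), path="")


# ---------------------------------------------------------------------------
# strict nested construction (unknown keys rejected with names)
# ---------------------------------------------------------------------------

_NESTED = {
    "natural_history": NaturalHistoryParams,
    "test": TestCharacteristics,
    "participation": ParticipationParams,
    "utilities": UtilityParams,
    "costs": CostParams,
    "survival": SurvivalParams,
    "demographics": DemographicParams,
    "risk_model": RiskModelParams,
}


def _build(cls, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise ParameterFormatError(f"expected a mapping at {path or '<root>'}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        where = path or "<root>"
        raise ParameterFormatError(f"unknown keys at {where}: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        sub = _NESTED.get(key) if cls is ModelParameters else None
        if sub is not None:
            kwargs[key] = _build(sub, value, f"{path}{key}.")
        elif cls is ModelParameters and key == "life_table":
            kwargs[key] = [_build(LifeTableRow, row, f"life_table[{i}].")
                           for i, row in enumerate(value)]
        else:
            kwargs[key] = value
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_parameter_set(path: str | Path) -> ModelParameters:
    """Load and validate a parameter file (YAML, nested keys).

    Raises :class:`ParameterFormatError` on parse failure or unknown keys and
    :class:`ParameterValidationError` if any model invariant is violated.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParameterFormatError(f"{path}: top level must be a mapping")
    params = ModelParameters.from_dict(raw)
    report = validate_parameters(params)
    report.raise_if_invalid()
    return params


def write_parameter_set(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to YAML; ``load(write(p)) == p``."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def export_json(params: ModelParameters, path: str | Path) -> None:
    """Export the validated set as JSON (interchange convenience)."""
    validate_parameters(params).raise_if_invalid()
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def import_life_table_csv(path: str | Path) -> list[LifeTableRow]:
    """Read a life table from CSV with columns age,sex,all_cause_rate,lung_cancer_rate."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"age", "sex", "all_cause_rate", "lung_cancer_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterFormatError(f"life-table CSV missing columns: {sorted(missing)}")
    return [LifeTableRow(int(r.age), str(r.sex), float(r.all_cause_rate),
                         float(r.lung_cancer_rate))
            for r in df.itertuples()]


def export_life_table_csv(rows: list[LifeTableRow], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[tuple[str, str]] = field(default_factory=list)

    def add(self, field_path: str, message: str) -> None:
        self.violations.append((field_path, message))

    @property
    def valid(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if not self.valid:
            from .errors import ParameterValidationError

            lines = "; ".join(f"{p}: {m}" for p, m in self.violations)
            raise ParameterValidationError(lines)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return "\n".join(f"{p}: {m}" for p, m in self.violations) or "<valid>"


def _check_prob(report: ValidationReport, path: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.add(path, f"probability {value} outside [0, 1]")


def validate_parameters(p: ModelParameters) -> ValidationReport:
    """Check every model invariant; the report is empty iff the set is valid."""
    r = ValidationReport()
    nh = p.natural_history
    if nh.onset_lognormal_sigma <= 0:
        r.add("natural_history.onset_lognormal_sigma", "must be > 0")
    if len(nh.progression_rate) != N_TRANSITIONS:
        r.add("natural_history.progression_rate",
              f"needs {N_TRANSITIONS} entries (one per stage transition)")
    if len(nh.presentation_rate) != N_STAGES:
        r.add("natural_history.presentation_rate",
              f"needs {N_STAGES} entries (one per stage)")
    for i, rate in enumerate(nh.progression_rate):
        if rate < 0:
            r.add(f"natural_history.progression_rate[{STAGES[i]}->{STAGES[i + 1]}]",
                  f"negative rate {rate}")
    for i, rate in enumerate(nh.presentation_rate):
        if rate < 0:
            r.add(f"natural_history.presentation_rate[{STAGES[i]}]", f"negative rate {rate}")
    if nh.frailty_variance < 0:
        r.add("natural_history.frailty_variance", "must be >= 0")

    _check_prob(r, "test.sensitivity", p.test.sensitivity)
    _check_prob(r, "test.specificity", p.test.specificity)
    _check_prob(r, "participation.p_response", p.participation.p_response)
    _check_prob(r, "participation.p_join_given_eligible", p.participation.p_join_given_eligible)

    u = p.utilities
    if len(u.baseline_male) != len(u.age_band_edges) or \
            len(u.baseline_female) != len(u.age_band_edges):
        r.add("utilities.age_band_edges", "baseline vectors must match band edges")
    for name, values in (("baseline_male", u.baseline_male),
                         ("baseline_female", u.baseline_female)):
        for i, v in enumerate(values):
            _check_prob(r, f"utilities.{name}[{i}]", v)
    for name in ("stage_II", "stage_III", "stage_IV", "disutility_screen", "disutility_fp"):
        _check_prob(r, f"utilities.{name}", getattr(u, name))
    for name in ("disutility_screen_duration_years", "disutility_fp_duration_years"):
        if getattr(u, name) <= 0:
            r.add(f"utilities.{name}", "duration must be > 0")

    c = p.costs
    for name in ("invite", "questionnaire_scoring", "followup_invite", "ldct_scan",
                 "fp_workup", "care_year2_factor", "end_of_life"):
        if getattr(c, name) < 0:
            r.add(f"costs.{name}", "cost must be >= 0")
    if len(c.care_year1) != N_STAGES:
        r.add("costs.care_year1", f"needs {N_STAGES} entries (one per stage)")
    for i, v in enumerate(c.care_year1):
        if v < 0:
            r.add(f"costs.care_year1[{STAGES[i]}]", "cost must be >= 0")

    s = p.survival
    if s.family != "exponential":
        r.add("survival.family", f"unsupported family {s.family!r}")
    if len(s.rate) != N_STAGES:
        r.add("survival.rate", f"needs {N_STAGES} entries (one per stage)")
    for i in range(1, len(s.rate)):
        if s.rate[i] < s.rate[i - 1]:
            r.add(f"survival.rate[{STAGES[i]}]",
                  "survival must be stochastically non-increasing in stage order "
                  "(rates must be non-decreasing)")
    for i, v in enumerate(s.rate):
        if v <= 0:
            r.add(f"survival.rate[{STAGES[i]}]", "rate must be > 0")

    d = p.demographics
    if not (55.0 <= d.age_min <= d.age_max <= 80.0):
        r.add("demographics.age_min/age_max", "entry ages must satisfy 55 <= min <= max <= 80")
    _check_prob(r, "demographics.p_male", d.p_male)
    _check_prob(r, "demographics.p_current_smoker", d.p_current_smoker)

    if p.risk_model.baseline_median_percent < 0:
        r.add("risk_model.baseline_median_percent", "must be >= 0")
    if p.risk_model.high_risk_multiplier < 1:
        r.add("risk_model.high_risk_multiplier", "must be >= 1")
    if p.risk_model.noise_sigma < 0:
        r.add("risk_model.noise_sigma", "must be >= 0")

    if p.discount_rate_annual < 0:
        r.add("discount_rate_annual", "must be >= 0")
    if p.pool_size < 1:
        r.add("pool_size", "must be >= 1")
    for factor in ("smoking_factor_current", "smoking_factor_former"):
        if getattr(p, factor) < 0:
            r.add(factor, "must be >= 0")

    seen: set[tuple[int, str]] = set()
    for i, row in enumerate(p.life_table):
        if row.all_cause_rate < 0:
            r.add(f"life_table[{i}]", f"negative all-cause rate at age {row.age}")
        if row.lung_cancer_rate < 0:
            r.add(f"life_table[{i}]", f"negative lung-cancer rate at age {row.age}")
        seen.add((row.age, row.sex))
    for sex in ("male", "female"):
        for age in range(int(math.floor(p.demographics.age_min)), p.life_table_closing_age):
            if (age, sex) not in seen:
                r.add("life_table", f"missing age {age} for sex {sex}")
                break
    return r


# ---------------------------------------------------------------------------
# bundled fixture parameter set
# ---------------------------------------------------------------------------

def _fixture_life_table(closing_age: int = 100) -> list[LifeTableRow]:
    """Synthetic smoker-population life table (Gompertz all-cause rates with a
    small lung-cancer component); a placeholder, not national statistics."""
    rows: list[LifeTableRow] = []
    for sex, scale in (("male", 1.0), ("female", 0.82)):
        for age in range(50, closing_age + 1):
            all_cause = scale * 5.0e-5 * math.exp(0.092 * age)
            lc = 5.0e-4 * math.exp(0.045 * (age - 55)) if age >= 55 else 2.0e-4
            rows.append(LifeTableRow(age, sex, round(all_cause, 8), round(lc, 8)))
    return rows


def default_parameter_fixture() -> ModelParameters:
    """Complete runnable parameter set.

    Published point values (test characteristics, participation, utilities,
    disutilities, LDCT unit cost, discount rate, pool size) appear exactly.
    The natural-history rates, stage survival rates, care costs, admin costs
    and the life table are PLACEHOLDERS chosen for plausible epidemiology;
    they are not the calibrated values behind the published results.
    """
    return ModelParameters(
        schema_version=SCHEMA_VERSION,
        natural_history=NaturalHistoryParams(
            onset_lognormal_mu=math.log(105.0),
            onset_lognormal_sigma=0.25,
            progression_rate=[1.4, 1.4, 1.2, 1.2, 1.0, 1.0],
            presentation_rate=[0.03, 0.06, 0.15, 0.25, 0.50, 0.70, 1.20],
        ),
        test=TestCharacteristics(sensitivity=0.709, specificity=0.624),
        participation=ParticipationParams(p_response=0.307, p_join_given_eligible=0.465),
        utilities=UtilityParams(
            age_band_edges=[55.0, 65.0, 75.0, 85.0],
            baseline_male=[0.8100, 0.8000, 0.7816, 0.7500],
            baseline_female=[0.7900, 0.7700, 0.7531, 0.7200],
        ),
        costs=CostParams(
            invite=1.50,
            questionnaire_scoring=2.50,
            followup_invite=5.00,
            ldct_scan=98.80,
            fp_workup=300.00,
            care_year1=[9000.0, 9500.0, 10500.0, 11000.0, 12000.0, 12500.0, 13000.0],
            care_year2_factor=0.30,
            end_of_life=3500.0,
        ),
        survival=SurvivalParams(
            family="exponential",
            # median post-dx survival ~8, 6, 4, 3, 1.8, 1.2, 0.6 years by stage
            rate=[0.0866, 0.1155, 0.1733, 0.2310, 0.3851, 0.5776, 1.1552],
        ),
        demographics=DemographicParams(),
        risk_model=RiskModelParams(),
        life_table=_fixture_life_table(),
    )
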