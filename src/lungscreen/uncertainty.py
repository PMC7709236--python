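"""Uncertainty analyses: univariate sensitivity, scenarios, and PSA/CEAC.

All layers hold common random numbers fixed (the pool seed is reused), so a
perturbed run differs from the base case only through the perturbation.
"""

from __future__ import annotations

import copy
import dataclasses
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimulatedPool, build_pool, net_monetary_benefit, run_grid, run_strategy
from .errors import ConfigurationError
from .params import ModelParameters, validate_parameters
from .screening import StrategySpec, full_strategy_grid

_INDEX = re.compile(r"^(\w+)\[(\d+)\]$")


# ---------------------------------------------------------------------------
# dotted-path access into the parameter tree
# ---------------------------------------------------------------------------

def get_path(params: ModelParameters, path: str):
    obj: object = params
    for part in path.split("."):
        m = _INDEX.match(part)
        try:
            if m:
                obj = getattr(obj, m.group(1))[int(m.group(2))]
            else:
                obj = getattr(obj, part)
        except (AttributeError, IndexError):
            raise ConfigurationError(f"unknown parameter path {path!r}") from None
    return obj


def set_path(params: ModelParameters, path: str, value) -> ModelParameters:
    """Return a deep copy of ``params`` with the leaf at ``path`` replaced."""
    get_path(params, path)  # raises ConfigurationError on unknown paths
    new = copy.deepcopy(params)
    parts = path.split(".")
    obj: object = new
    for part in parts[:-1]:
        m = _INDEX.match(part)
        obj = getattr(obj, m.group(1))[int(m.group(2))] if m else getattr(obj, part)
    last = parts[-1]
    m = _INDEX.match(last)
    if m:
        getattr(obj, m.group(1))[int(m.group(2))] = value
    else:
        setattr(obj, last, value)
    return new


_SKIP_FIELDS = {"schema_version", "pool_size", "price_year", "life_table",
                "life_table_closing_age", "currency", "extensions",
                "population_smokers_55_80"}


def scalar_parameter_paths(params: ModelParameters) -> list[str]:
    """Dotted paths of every perturbable numeric leaf of the parameter set."""
    paths: list[str] = []

    def walk(obj, prefix: str):
        for f in dataclasses.fields(obj):
            if prefix == "" and f.name in _SKIP_FIELDS:
                continue
            value = getattr(obj, f.name)
            path = f"{prefix}{f.name}"
            if dataclasses.is_dataclass(value):
                walk(value, path + ".")
            elif isinstance(value, list) and value and isinstance(value[0], (int, float)):
                paths.extend(f"{path}[{i}]" for i in range(len(value)))
            elif isinstance(value, (int, float)) and not isinstance(value, bool):
                paths.append(path)

    walk(params, "")
    return paths


# ---------------------------------------------------------------------------
# univariate (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

def univariate_sa(base: ModelParameters, spec: StrategySpec, delta: float,
                  seed: int, pool_n: int | None = None,
                  paths: Sequence[str] | None = None) -> pd.DataFrame:
    """Perturb each scalar parameter by a +/- fraction and record the ICER
    versus no screening both ways, holding CRN (the pool seed) fixed.

    Rows whose perturbation violates a parameter invariant are flagged in the
    ``valid`` column rather than dropped.  The table is sorted by the width
    of the ICER range (the tornado ordering).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    paths = list(paths) if paths is not None else scalar_parameter_paths(base)

    def icer_for(params: ModelParameters) -> float | None:
        pool = build_pool(params, seed=seed, n=pool_n)
        return run_strategy(pool, spec).icer_vs_none

    base_icer = icer_for(base)
    rows = []
    for path in paths:
        value = get_path(base, path)
        entry = {"parameter": path, "base_value": value, "valid": True,
                 "icer_low": None, "icer_high": None}
        for side, factor in (("icer_low", 1.0 - delta), ("icer_high", 1.0 + delta)):
            perturbed = set_path(base, path, value * factor)
            if not validate_parameters(perturbed).valid:
                entry["valid"] = False
                continue
            entry[side] = icer_for(perturbed)
        lo, hi = entry["icer_low"], entry["icer_high"]
        entry["range"] = abs(hi - lo) if (lo is not None and hi is not None) else np.nan
        rows.append(entry)
    df = pd.DataFrame(rows)
    df["base_icer"] = base_icer
    return df.sort_values("range", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    name: str
    overrides: dict[str, object] = field(default_factory=dict)


def builtin_scenarios() -> list[ScenarioSpec]:
    """The named alternative-assumption scenarios shipped with the model."""
    return [
        ScenarioSpec("fp_disutility_zero", {"utilities.disutility_fp": 0.0}),
        ScenarioSpec("discount_zero", {"discount_rate_annual": 0.0}),
        ScenarioSpec("heterogeneity_on", {"natural_history.heterogeneity": True,
                                          "natural_history.frailty_variance": 0.25}),
    ]


def apply_scenario(base: ModelParameters, scenario: ScenarioSpec) -> ModelParameters:
    params = base
    for path, value in scenario.overrides.items():
        params = set_path(params, path, value)
    return params


def run_scenarios(registry: Sequence[ScenarioSpec], base: ModelParameters,
                  specs: Sequence[StrategySpec] | None = None,
                  seed: int = 0, pool_n: int | None = None) -> dict[str, list]:
    """Re-run the strategy grid under each scenario's overrides (CRN fixed)."""
    if not registry:
        raise ValueError("scenario registry must be nonempty")
    out: dict[str, list] = {}
    for scenario in registry:
        params = apply_scenario(base, scenario)
        pool = build_pool(params, seed=seed, n=pool_n)
        out[scenario.name] = run_grid(pool, specs)
    return out


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def beta_from_mean(mean: float, ess: float = 100.0):
    from scipy import stats

    return stats.beta(mean * ess, (1.0 - mean) * ess)


def gamma_from_mean(mean: float, cv: float = 0.2):
    from scipy import stats

    shape = 1.0 / cv ** 2
    return stats.gamma(shape, scale=mean / shape)


def default_psa_distributions(params: ModelParameters) -> dict[str, object]:
    """Beta for probabilities/utilities, gamma for costs and rates, per the
    conventional second-order assignment; keyed by parameter path."""
    return {
        "test.sensitivity": beta_from_mean(params.test.sensitivity),
        "test.specificity": beta_from_mean(params.test.specificity),
        "participation.p_response": beta_from_mean(params.participation.p_response),
        "participation.p_join_given_eligible":
            beta_from_mean(params.participation.p_join_given_eligible),
        "costs.ldct_scan": gamma_from_mean(params.costs.ldct_scan),
        "costs.fp_workup": gamma_from_mean(params.costs.fp_workup),
        "costs.end_of_life": gamma_from_mean(params.costs.end_of_life),
        "utilities.disutility_fp": beta_from_mean(params.utilities.disutility_fp, ess=50.0),
        "natural_history.presentation_rate[0]":
            gamma_from_mean(params.natural_history.presentation_rate[0]),
    }


def run_psa(distributions: dict[str, object], n_draws: int,
            base: ModelParameters, thresholds: Sequence[float],
            specs: Sequence[StrategySpec] | None = None,
            inner_pool_n: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Sample parameter vectors, re-run the grid per draw on a reduced inner
    pool, and tabulate the cost-effectiveness acceptability curve.

    Returns a tidy frame (threshold, strategy, probability); probabilities
    sum to one across strategies at each threshold (each draw has exactly one
    NMB winner; the no-screening comparator is always a candidate).
    """
    for path in distributions:
        get_path(base, path)  # unknown paths -> ConfigurationError
    specs = list(specs) if specs is not None else full_strategy_grid()
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0x55))))
    wins: dict[float, dict[str, int]] = {t: {} for t in thresholds}
    for draw in range(n_draws):
        params = base
        for path, dist in distributions.items():
            params = set_path(params, path, float(dist.rvs(random_state=rng)))
        pool = build_pool(params, seed=seed, n=inner_pool_n)
        results = run_grid(pool, specs)
        for t in thresholds:
            winner = max(results, key=lambda res: net_monetary_benefit(res, t))
            wins[t][winner.strategy] = wins[t].get(winner.strategy, 0) + 1
    rows = [{"threshold": t, "strategy": name, "probability": count / n_draws}
            for t, counts in wins.items() for name, count in counts.items()]
    return pd.DataFrame(rows)
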