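"""Bayesian calibration of natural-history and test parameters.

Trial-style summary targets (counts over denominators, binomial or Poisson)
are compared with summaries simulated from a cohort run through a three-round
trial-protocol screening design.  The simulated likelihood holds the
underlying uniform draws fixed across proposals (common random numbers), so
the log-posterior surface is a deterministic function of the parameters and
chains are bit-reproducible given a seed.  Sampling is random-walk Metropolis
on log-transformed parameters.

Observed trial counts are NOT bundled; a synthetic-target generator and the
CSV target schema (name, count, denominator, family) let transcribed targets
be dropped in.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .params import NaturalHistoryParams
from .stages import EARLY_STAGE_INDICES, N_STAGES

TRIAL_ROUNDS = (0.0, 1.0, 2.0)        # screen offsets, years from entry
TRIAL_ENTRY_AGES = (55.0, 74.0)       # trial-protocol entry age range
CLINICAL_HORIZON = 3.0                # years, short-term clinical incidence window

#: calibratable parameter names -> how they modify the base configuration
CALIBRATED_PARAMS = ("sensitivity", "onset_median_age", "onset_sigma",
                     "progression_scale", "presentation_scale")


@dataclass
class CalibrationTarget:
    name: str
    count: int
    denominator: int
    family: str = "binomial"   # "binomial" | "poisson"

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValueError(f"{self.name}: denominator must be > 0")
        if self.family == "binomial" and self.count > self.denominator:
            raise ValueError(f"{self.name}: count exceeds denominator")


def targets_to_csv(targets: list[CalibrationTarget], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(t) for t in targets]).to_csv(path, index=False)


def targets_from_csv(path: str | Path) -> list[CalibrationTarget]:
    import pandas as pd

    df = pd.read_csv(path)
    return [CalibrationTarget(str(r.name), int(r.count), int(r.denominator), str(r.family))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# vectorised cohort simulator
# ---------------------------------------------------------------------------

def _base_uniforms(n: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0xCA1))))
    return {
        "z_onset": rng.standard_normal(n),
        "u_entry": rng.random(n),
        "u_prog": rng.random((n, N_STAGES - 1)),
        "u_pres": rng.random((n, N_STAGES)),
        "u_screen": rng.random((n, len(TRIAL_ROUNDS))),
    }


def simulate_summaries(nh: NaturalHistoryParams, sensitivity: float,
                       n: int, seed: int) -> dict[str, float]:
    """Trial-shaped summary proportions from a fixed-seed simulated cohort.

    Returns screen-detection proportions per round, the early-stage share of
    screen-detected cancers, and short-term clinical incidence among the
    undetected.  Identical seed (and n) gives identical summaries for any
    parameter values, because the same uniforms are inverse-CDF transformed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    u = _base_uniforms(n, seed)
    entry = TRIAL_ENTRY_AGES[0] + (TRIAL_ENTRY_AGES[1] - TRIAL_ENTRY_AGES[0]) * u["u_entry"]
    onset = np.exp(nh.onset_lognormal_mu + nh.onset_lognormal_sigma * u["z_onset"])
    has_onset = onset <= 100.0

    prog = np.asarray(nh.progression_rate, dtype=float)
    pres = np.asarray(nh.presentation_rate, dtype=float)
    with np.errstate(divide="ignore"):
        t_prog = np.where(prog > 0, -np.log(u["u_prog"]) / np.where(prog > 0, prog, 1.0),
                          np.inf)
        t_pres = np.where(pres > 0, -np.log(u["u_pres"]) / np.where(pres > 0, pres, 1.0),
                          np.inf)

    stage_entry = np.full((n, N_STAGES), np.inf)
    stage_entry[:, 0] = np.where(has_onset, onset, np.inf)
    presentation = np.full(n, np.inf)
    pres_stage = np.full(n, -1)
    alive_clock = has_onset.copy()
    for s in range(N_STAGES):
        dt_prog = t_prog[:, s] if s < N_STAGES - 1 else np.full(n, np.inf)
        dt_pres = t_pres[:, s]
        presents = alive_clock & (dt_pres <= dt_prog) & np.isfinite(dt_pres)
        presentation[presents] = stage_entry[presents, s] + dt_pres[presents]
        pres_stage[presents] = s
        stalls = alive_clock & (dt_pres <= dt_prog) & ~np.isfinite(dt_pres)
        alive_clock &= ~(presents | stalls)
        if s < N_STAGES - 1:
            stage_entry[alive_clock, s + 1] = stage_entry[alive_clock, s] + dt_prog[alive_clock]

    # simulants already presenting before entry cannot enrol; treat as disease-free
    enrolled_diseased = has_onset & (presentation >= entry)
    onset_eff = np.where(enrolled_diseased, onset, np.inf)

    detected = np.zeros(n, dtype=bool)
    det_round = np.full(n, -1)
    det_stage = np.full(n, -1)
    for k, offset in enumerate(TRIAL_ROUNDS):
        t = entry + offset
        occult = (~detected) & enrolled_diseased & (onset_eff <= t) & (presentation > t)
        hit = occult & (u["u_screen"][:, k] < sensitivity)
        occupied = np.clip(np.sum(stage_entry <= t[:, None], axis=1) - 1, 0, N_STAGES - 1)
        det_round[hit] = k
        det_stage[hit] = occupied[hit]
        detected |= hit

    n_det = int(detected.sum())
    early = np.isin(det_stage, list(EARLY_STAGE_INDICES)) & detected
    clinical_3yr = (~detected) & enrolled_diseased & (presentation <= entry + CLINICAL_HORIZON)

    out = {f"det_round_{k + 1}": float(np.mean(det_round == k))
           for k in range(len(TRIAL_ROUNDS))}
    out["early_share_detected"] = float(early.sum() / n_det) if n_det else 0.0
    out["clinical_3yr"] = float(clinical_3yr.mean())
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_likelihood(sim: dict[str, float], targets: list[CalibrationTarget]) -> float:
    """Sum of binomial/Poisson log-pmfs of the observed counts at the
    simulated proportions; -inf when an observed count has zero simulated
    probability."""
    total = 0.0
    for t in targets:
        if t.name not in sim:
            raise ValueError(f"no simulated summary named {t.name!r}")
        p = sim[t.name]
        if t.family == "binomial":
            total += float(stats.binom.logpmf(t.count, t.denominator, p))
        elif t.family == "poisson":
            mu = p * t.denominator
            if mu == 0.0:
                total += 0.0 if t.count == 0 else -math.inf
            else:
                total += float(stats.poisson.logpmf(t.count, mu))
        else:
            raise ValueError(f"unknown likelihood family {t.family!r}")
    return total


# ---------------------------------------------------------------------------
# parameter vector plumbing
# ---------------------------------------------------------------------------

def apply_calibrated(base_nh: NaturalHistoryParams, base_sensitivity: float,
                     theta: dict[str, float]) -> tuple[NaturalHistoryParams, float]:
    """Overlay a calibrated parameter vector on a base configuration."""
    unknown = set(theta) - set(CALIBRATED_PARAMS)
    if unknown:
        raise ValueError(f"unknown calibrated parameters: {sorted(unknown)}")
    nh = dataclasses.replace(
        base_nh,
        progression_rate=list(base_nh.progression_rate),
        presentation_rate=list(base_nh.presentation_rate),
    )
    sens = theta.get("sensitivity", base_sensitivity)
    if "onset_median_age" in theta:
        nh.onset_lognormal_mu = math.log(theta["onset_median_age"])
    if "onset_sigma" in theta:
        nh.onset_lognormal_sigma = theta["onset_sigma"]
    if "progression_scale" in theta:
        nh.progression_rate = [r * theta["progression_scale"] for r in nh.progression_rate]
    if "presentation_scale" in theta:
        nh.presentation_rate = [r * theta["presentation_scale"] for r in nh.presentation_rate]
    return nh, sens


# ---------------------------------------------------------------------------
# random-walk Metropolis
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    param_names: list[str]
    draws: np.ndarray            # (kept iterations, n_params), natural scale
    log_posterior: np.ndarray    # per kept iteration
    acceptance_rate: float
    seed: int

    def mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.draws.mean(axis=0)))

    def credible_interval(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        return {name: (float(np.percentile(self.draws[:, j], lo)),
                       float(np.percentile(self.draws[:, j], hi)))
                for j, name in enumerate(self.param_names)}

    def diagnostics(self) -> dict:
        return {"acceptance_rate": self.acceptance_rate,
                "n_draws": int(self.draws.shape[0]),
                "posterior_mean": self.mean(),
                "ci95": {k: list(v) for k, v in self.credible_interval().items()}}


def run_mcmc(priors: dict[str, "stats.rv_continuous | object"],
             targets: list[CalibrationTarget],
             base_nh: NaturalHistoryParams, base_sensitivity: float,
             iterations: int = 4000, burn_in_fraction: float = 0.5,
             proposal_scale: float | dict[str, float] = 0.1,
             cohort_n: int = 2000, seed: int = 0,
             init: dict[str, float] | None = None) -> PosteriorSample:
    """Random-walk Metropolis on log-transformed calibrated parameters.

    ``priors`` maps parameter names to frozen scipy distributions on the
    natural (positive) scale; the walk runs on log-parameters with the
    appropriate Jacobian.  The simulated likelihood is CRN-fixed: the cohort
    uniforms depend only on ``seed`` and ``cohort_n``.
    """
    names = sorted(priors)
    k = len(names)
    scales = np.array([proposal_scale[n] if isinstance(proposal_scale, dict)
                       else proposal_scale for n in names])

    if init is None:
        init = {n: float(priors[n].median()) for n in names}
    x = np.array([init[n] for n in names], dtype=float)
    sim_seed = seed + 1_000_003  # CRN seed for the simulated likelihood

    def log_post(xvec: np.ndarray) -> float:
        lp = sum(float(priors[n].logpdf(v)) for n, v in zip(names, xvec))
        if not math.isfinite(lp):
            return -math.inf
        theta = dict(zip(names, xvec))
        nh, sens = apply_calibrated(base_nh, base_sensitivity, theta)
        return lp + log_likelihood(simulate_summaries(nh, sens, cohort_n, sim_seed), targets)

    lp = log_post(x)
    if not math.isfinite(lp):
        raise ValueError("zero prior or likelihood mass at the initial point")

    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0x3C))))
    logx = np.log(x)
    chain = np.empty((iterations, k))
    lps = np.empty(iterations)
    accepts = 0
    for it in range(iterations):
        prop_log = logx + scales * rng.standard_normal(k)
        prop = np.exp(prop_log)
        lp_prop = log_post(prop)
        # Jacobian of the log transform: + sum(log x)
        log_ratio = (lp_prop + prop_log.sum()) - (lp + logx.sum())
        if math.log(rng.random()) < log_ratio:
            logx, x, lp = prop_log, prop, lp_prop
            accepts += 1
        chain[it] = x
        lps[it] = lp
    keep = slice(int(iterations * burn_in_fraction), None)
    return PosteriorSample(param_names=names, draws=chain[keep],
                           log_posterior=lps[keep],
                           acceptance_rate=accepts / iterations, seed=seed)


def synthetic_targets(true_theta: dict[str, float], base_nh: NaturalHistoryParams,
                      base_sensitivity: float, denominators: dict[str, int],
                      cohort_n: int, seed: int) -> list[CalibrationTarget]:
    """Generate observed-count targets from known parameters, with binomial
    sampling noise — the input to parameter-recovery validation."""
    nh, sens = apply_calibrated(base_nh, base_sensitivity, true_theta)
    sim = simulate_summaries(nh, sens, cohort_n, seed + 77)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, 0x5E))))
    out = []
    for name, denom in denominators.items():
        p = sim[name]
        out.append(CalibrationTarget(name=name, count=int(rng.binomial(denom, p)),
                                     denominator=denom, family="binomial"))
    return out
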