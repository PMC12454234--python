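"""Synthetic data generator: log-binomial random-intercept outcomes over
four visits with monotone MAR dropout.

Each participant i contributes 4 visit rows sharing baseline covariates
and a Gaussian random intercept eta_i0 ~ N(0, tau^2).  Outcomes follow the
log-linear (risk-ratio scale) mixed model

    log Pr(Y_ij = 1) = eta_i0 + b0 + b1*treatment + b2*baseline
                       + b3*center + b4*gender + b5*age_c,

so exp(b1) is the true subject-specific risk ratio of treatment.  The
intercept b0 is calibrated by Monte-Carlo bisection so the overall event
frequency hits a target (Pevent); probabilities that exceed 1 — the
log-link's invalid region — are clipped at 1 - 1e-8 and counted.

From visit 2 on, a participant still in the study drops out with
probability expit(xi0 + log(1.5) * Y_{i,j-1}); dropout is monotone (all
later outcomes missing) and xi0 is calibrated so a target fraction of
participants (20% by default) ever drop out.  Missingness depends only on
the previously observed outcome, hence MAR.

Covariates are synthetic stand-ins for a resampled respiratory-trial
population: four Bernoulli(0.5) baseline indicators and an integer age
uniform on [11, 68], centered at its design mean (39.5) before entering
the linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ClusteredDataset

__all__ = [
    "ScenarioConfig",
    "generate_covariates",
    "simulate_outcomes",
    "calibrate_intercept",
    "calibrate_dropout_intercept",
    "calibrate",
    "apply_mar_dropout",
    "simulate_dataset",
]

COVARIATES = ["treatment", "baseline", "center", "gender", "age"]

#: clip ceiling for log-link probabilities that land above 1
P_CLIP = 1.0 - 1e-8
#: floor returned by dropout calibration when the target is (near) zero
XI0_FLOOR = -15.0

AGE_RANGE = (11, 68)
AGE_CENTER = (AGE_RANGE[0] + AGE_RANGE[1]) / 2.0  # 39.5


@dataclass
class ScenarioConfig:
    """One simulation cell.

    ``beta_rest`` are the baseline-symptom, center, gender and age
    coefficients; defaults are the respiratory-study estimates used
    throughout the evaluation grid.  ``beta0`` and ``xi0`` may be left
    None and calibrated with :func:`calibrate`.
    """

    N: int = 100
    p_event: float = 0.40
    tau: float = 0.02
    beta1: float = np.log(1.60)
    beta_rest: tuple = (0.71, 0.28, -0.05, -0.01)
    beta0: float | None = None
    dropout_or: float = 1.50
    dropout_rate: float = 0.20
    xi0: float | None = None
    visits: int = 4
    dropout_metric: str = "participant"  # or "visit": fraction of slots missing

    def __post_init__(self):
        if not 0.0 < self.p_event < 1.0:
            raise ValueError("p_event must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.visits < 2:
            raise ValueError("visits must be >= 2")

    @property
    def beta(self) -> np.ndarray:
        """(b1..b5) fixed-effect vector excluding the intercept."""
        return np.array([self.beta1, *self.beta_rest])


def _draw_covariates(rng: np.random.Generator, n: int) -> np.ndarray:
    """n x 5 participant-level covariate matrix (age already centered)."""
    bern = rng.integers(0, 2, size=(n, 4)).astype(float)
    age = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n).astype(float)
    return np.column_stack([bern, age - AGE_CENTER])


def generate_covariates(config: ScenarioConfig, rng: np.random.Generator) -> ClusteredDataset:
    """Participant covariates expanded to one row per visit (y missing)."""
    Z = _draw_covariates(rng, config.N)
    v = config.visits
    rows = np.repeat(Z, v, axis=0)
    df = pd.DataFrame(rows, columns=COVARIATES)
    df.insert(0, "cluster", np.repeat(np.arange(1, config.N + 1), v))
    df.insert(1, "y", np.nan)
    df["visit"] = np.tile(np.arange(1, v + 1), config.N)
    ds = ClusteredDataset(df, validate=False)
    return ds


def _event_probs(Z: np.ndarray, beta0: float, config: ScenarioConfig,
                 eta: np.ndarray) -> tuple[np.ndarray, float]:
    """Clipped per-participant event probabilities and the clip fraction."""
    lin = beta0 + Z @ config.beta + eta
    p = np.exp(lin)
    clipped = p >= 1.0
    p = np.where(clipped, P_CLIP, p)
    return p, float(clipped.mean())


def simulate_outcomes(covariates: ClusteredDataset, config: ScenarioConfig,
                      rng: np.random.Generator) -> ClusteredDataset:
    """Draw log-binomial outcomes given covariates.

    Covariates are constant within a participant, so one probability per
    participant applies to all visits.  The clip fraction is stored on the
    returned dataset as ``clip_fraction`` and warned about above 1%.
    """
    if config.beta0 is None:
        raise ValueError("beta0 is not set; run calibrate_intercept first")
    df = covariates.df.copy()
    v = config.visits
    Z = df[COVARIATES].to_numpy(float)[::v]
    eta = rng.normal(0.0, config.tau, size=config.N)
    p, clip_frac = _event_probs(Z, config.beta0, config, eta)
    y = (rng.random((config.N, v)) < p[:, None]).astype(float)
    df["y"] = y.ravel()
    if clip_frac > 0.01:
        warnings.warn(
            f"{clip_frac:.1%} of participants had log-link probability >= 1 "
            "(clipped); the scenario strains the log-link's valid region",
            stacklevel=2,
        )
    out = ClusteredDataset(df, validate=False)
    out.clip_fraction = clip_frac
    return out


def _bisect(fn, lo, hi, target, tol, max_iter=200):
    """Monotone-increasing bisection of fn to |fn - target| < tol."""
    flo, fhi = fn(lo), fn(hi)
    if not (flo <= target <= fhi):
        raise ValueError(
            f"target {target} outside bracket [{flo:.4g}, {fhi:.4g}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = fn(mid)
        if abs(fm - target) < tol:
            return mid
        if fm < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_intercept(config: ScenarioConfig, rng: np.random.Generator,
                        n_mc: int = 100_000, tol: float = 0.002) -> float:
    """Bisection for beta0 so the Monte-Carlo mean event probability hits
    the target overall event frequency.

    Uses common random numbers: one draw of ``n_mc`` participants (and
    random intercepts) reused across every bisection evaluation, making
    the objective a deterministic monotone function of beta0.
    """
    Z = _draw_covariates(rng, n_mc)
    eta = rng.normal(0.0, config.tau, size=n_mc)

    def mean_event(b0):
        p, _ = _event_probs(Z, b0, config, eta)
        return float(p.mean())

    beta0 = _bisect(mean_event, -25.0, 5.0, config.p_event, tol)
    _, clip_frac = _event_probs(Z, beta0, config, eta)
    if clip_frac > 0.01:
        raise ValueError(
            f"event frequency {config.p_event} is unreachable without clipping "
            f"{clip_frac:.1%} of probabilities above 1; rescale covariates or "
            "lower the target"
        )
    return float(beta0)


def _dropout_prob_paths(Y: np.ndarray, xi0: float, config: ScenarioConfig,
                        metric: str) -> float:
    """Expected dropout measure given complete outcome paths Y (n x visits)."""
    log_or = np.log(config.dropout_or)
    hazards = expit(xi0 + log_or * Y[:, : config.visits - 1])  # visits 2..V
    surv = np.cumprod(1.0 - hazards, axis=1)
    if metric == "participant":
        return float(1.0 - surv[:, -1].mean())
    # expected fraction of visit slots missing: dropping at visit j wipes
    # visits j..V
    drop_at = hazards * np.column_stack([np.ones(len(Y)), surv[:, :-1]])
    slots_lost = drop_at @ np.arange(config.visits - 1, 0, -1)
    return float(slots_lost.mean() / config.visits)


def calibrate_dropout_intercept(config: ScenarioConfig, rng: np.random.Generator,
                                n_mc: int = 100_000, tol: float = 0.002) -> float:
    """Bisection for xi0 so the expected dropout measure hits the target.

    The dropout measure defaults to the fraction of participants who ever
    drop out ("total dropout rate"); set ``dropout_metric='visit'`` for
    the fraction of visit slots missing.  Outcome paths are simulated once
    with common random numbers, and the exact conditional dropout
    probability given each path is averaged, so the objective is smooth
    and monotone in xi0.
    """
    if config.beta0 is None:
        config = replace(config, beta0=calibrate_intercept(config, rng, n_mc, tol))
    if config.dropout_rate <= 0.0:
        warnings.warn("dropout target is zero; returning the floor xi0",
                      stacklevel=2)
        return XI0_FLOOR
    Z = _draw_covariates(rng, n_mc)
    eta = rng.normal(0.0, config.tau, size=n_mc)
    p, _ = _event_probs(Z, config.beta0, config, eta)
    Y = (rng.random((n_mc, config.visits)) < p[:, None]).astype(float)

    def rate(xi0):
        return _dropout_prob_paths(Y, xi0, config, config.dropout_metric)

    try:
        return float(_bisect(rate, XI0_FLOOR, 5.0, config.dropout_rate, tol))
    except ValueError:
        warnings.warn(
            f"dropout target {config.dropout_rate} below the floor; returning "
            f"xi0 = {XI0_FLOOR}", stacklevel=2)
        return XI0_FLOOR


def calibrate(config: ScenarioConfig, rng: np.random.Generator,
              n_mc: int = 100_000) -> ScenarioConfig:
    """Fill beta0 (and xi0 when dropout is on) by Monte-Carlo bisection."""
    beta0 = (config.beta0 if config.beta0 is not None
             else calibrate_intercept(config, rng))
    config = replace(config, beta0=beta0)
    if config.dropout_rate > 0.0 and config.xi0 is None:
        config = replace(config,
                         xi0=calibrate_dropout_intercept(config, rng, n_mc))
    return config


def apply_mar_dropout(data: ClusteredDataset, config: ScenarioConfig,
                      rng: np.random.Generator) -> ClusteredDataset:
    """Monotone MAR dropout: from visit 2 on, a participant still in the
    study drops with probability expit(xi0 + log(OR) * Y_prev); outcomes
    from the dropout visit onward become missing.  Visit-1 outcomes are
    never missing."""
    if config.xi0 is None:
        raise ValueError("xi0 is not set; run calibrate_dropout_intercept first")
    df = data.df.copy()
    v = config.visits
    Y = df["y"].to_numpy(float).reshape(-1, v)
    n = Y.shape[0]
    log_or = np.log(config.dropout_or)
    hazards = expit(config.xi0 + log_or * Y[:, : v - 1])
    draws = rng.random((n, v - 1)) < hazards
    out = Y.copy()
    active = np.ones(n, bool)
    for j in range(1, v):  # visit j+1 (0-based column j)
        dropped = active & draws[:, j - 1]
        out[dropped, j:] = np.nan
        active &= ~dropped
    df["y"] = out.ravel()
    res = ClusteredDataset(df, validate=False)
    res.clip_fraction = getattr(data, "clip_fraction", np.nan)
    return res


def simulate_dataset(config: ScenarioConfig, rng: np.random.Generator) -> ClusteredDataset:
    """Covariates -> outcomes -> dropout for one replicate.

    Requires a calibrated config (see :func:`calibrate`); dropout is
    skipped when ``dropout_rate`` is 0.
    """
    cov = generate_covariates(config, rng)
    data = simulate_outcomes(cov, config, rng)
    if config.dropout_rate > 0.0:
        data = apply_mar_dropout(data, config, rng)
    return data
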