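"""User-facing risk-ratio estimator for clustered binary data.

Pipeline: drop rows with missing outcomes (direct likelihood), augment
events with zero-outcome pseudo copies, fit the random-intercept logistic
GLMM by maximum likelihood, exponentiate the coefficients.  On the
augmented data the fitted odds equal the original risks, so exp(beta_hat)
estimates subject-specific risk ratios rather than odds ratios.
Uncertainty comes from the cluster nonparametric bootstrap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .augment import make_pseudo_observations
from .bootstrap import BootstrapResult, bootstrap_estimates, bootstrap_pvalue, percentile_ci
from .data import ClusteredDataset, ModelSpec
from .glmm import GLMMFit, fit_logistic_glmm

__all__ = ["RiskRatioResult", "estimate_risk_ratios"]


@dataclass
class RiskRatioResult:
    """Risk-ratio estimates with bootstrap uncertainty.

    All vectors align with ``names``.  ``tau`` is the random-intercept SD
    from the single observed-data augmented fit; bootstrap tau samples are
    available on ``boot`` but are not summarized into an interval.
    """

    names: list[str]
    log_rr: np.ndarray
    tau: float
    fit: GLMMFit
    level: float = 0.95
    B: int = 0
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    se_boot: np.ndarray | None = None
    p_boot: np.ndarray | None = None
    boot: BootstrapResult | None = None
    ci_flags: list[str] = field(default_factory=list)

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def coef(self, name: str) -> float:
        return float(self.log_rr[self.names.index(name)])

    def risk_ratio(self, name: str) -> float:
        return float(np.exp(self.coef(name)))

    def to_dict(self) -> dict:
        out = {
            "coefficients": {}, "tau": self.tau, "level": self.level, "B": self.B,
            "converged": self.fit.converged, "boundary_tau": self.fit.boundary_tau,
            "loglik": self.fit.loglik, "n_agq": self.fit.n_agq,
        }
        for k, name in enumerate(self.names):
            row = {"log_rr": float(self.log_rr[k]), "rr": float(np.exp(self.log_rr[k]))}
            if self.ci_lower is not None:
                row.update(
                    ci_lower=float(np.exp(self.ci_lower[k])),
                    ci_upper=float(np.exp(self.ci_upper[k])),
                    se_boot=float(self.se_boot[k]),
                    p_boot=float(self.p_boot[k]),
                )
            out["coefficients"][name] = row
        if self.ci_flags:
            out["ci_flags"] = self.ci_flags
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def estimate_risk_ratios(data: ClusteredDataset, spec: ModelSpec | None = None,
                         B: int = 1000, seed: int | None = None,
                         level: float = 0.95, n_jobs: int = 1) -> RiskRatioResult:
    """Estimate subject-specific risk ratios by pseudo-observation augmentation.

    Parameters
    ----------
    data
        Un-augmented long-format dataset; rows with missing outcomes are
        dropped internally (valid under MAR by the direct-likelihood
        principle).
    B
        Bootstrap resamples; 0 gives point estimates only.  Values below
        1000 give unstable limits; below 50 a warning is raised.
    seed
        Seed for the bootstrap streams; fixing it makes the whole result
        deterministic.
    """
    if spec is None:
        spec = ModelSpec(covariates=data.covariate_names)
    if 0 < B < 50:
        warnings.warn(
            f"B={B} bootstrap resamples give unstable confidence limits; "
            "B >= 1000 is recommended", stacklevel=2,
        )
    observed = data.drop_missing_outcomes()
    augmented = make_pseudo_observations(observed)
    fit = fit_logistic_glmm(augmented, spec)
    result = RiskRatioResult(
        names=list(spec.term_names), log_rr=fit.beta.copy(), tau=fit.tau,
        fit=fit, level=level, B=B,
    )
    if B > 0:
        start = np.append(fit.beta, np.log(fit.tau) if fit.tau > 0 else np.log(0.05))
        boot = bootstrap_estimates(data, spec, B=B, seed=seed, n_jobs=n_jobs,
                                   start=start)
        p = len(result.names)
        lo = np.empty(p)
        hi = np.empty(p)
        for k in range(p):
            lo[k], hi[k] = percentile_ci(boot.samples[:, k], level)
            if not (lo[k] <= fit.beta[k] <= hi[k]):
                result.ci_flags.append(
                    f"{result.names[k]}: point estimate outside percentile interval"
                )
        result.ci_lower, result.ci_upper = lo, hi
        result.se_boot = boot.samples.std(axis=0, ddof=1)
        result.p_boot = np.array(
            [bootstrap_pvalue(boot.samples[:, k]) for k in range(p)]
        )
        result.boot = boot
    return result
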