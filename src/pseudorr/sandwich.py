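"""Cluster-robust sandwich variance for the augmented-data pseudo-likelihood.

Provided as a comparator only.  The augmented dataset contains artificial
duplicated rows, so the ordinary estimating-equation argument behind the
sandwich A^{-1} B A^{-T} does not apply and the resulting standard errors
are biased even in large samples; the cluster bootstrap is the supported
inference method.  Derivatives are taken by central finite differences —
clarity over speed, since this module exists as a warning.

The variance is reported on the (beta, log tau) scale; the delta method
gives Var(tau) = tau^2 * Var(log tau).
"""

from __future__ import annotations

import numpy as np

from .data import ClusteredDataset, ModelSpec
from .glmm import GLMMFit, _AGQProblem

__all__ = ["cluster_scores", "sandwich_variance"]

_REL_STEP = 1e-5


def _per_cluster_fn(fit: GLMMFit, data: ClusteredDataset, spec: ModelSpec):
    """Return (theta_hat, f) where f(theta) -> per-cluster log-likelihoods."""
    y, X, codes = data.design(spec)
    prob = _AGQProblem(y, X, codes, spec.n_nodes)
    p = X.shape[1]
    if fit.boundary_tau:
        theta = np.asarray(fit.beta, float)

        def f(th):
            return prob.per_cluster_loglik(th, 0.0)
    else:
        theta = np.append(fit.beta, np.log(fit.tau))

        def f(th):
            return prob.per_cluster_loglik(th[:p], float(np.exp(th[p])))

    return theta, f


def cluster_scores(fit: GLMMFit, augmented_data: ClusteredDataset,
                   spec: ModelSpec | None = None) -> np.ndarray:
    """N x d matrix of per-cluster score vectors at the estimate.

    Central finite differences with step 1e-5 * max(1, |theta_r|).  At the
    MLE the column sums vanish (score equation), which tests assert.
    """
    if not fit.converged:
        raise ValueError("scores require a converged fit")
    if spec is None:
        spec = ModelSpec(covariates=augmented_data.covariate_names)
    theta, f = _per_cluster_fn(fit, augmented_data, spec)
    d = theta.size
    scores = np.empty((augmented_data.n_clusters, d))
    for r in range(d):
        h = _REL_STEP * max(1.0, abs(theta[r]))
        tp, tm = theta.copy(), theta.copy()
        tp[r] += h
        tm[r] -= h
        scores[:, r] = (f(tp) - f(tm)) / (2.0 * h)
    return scores


def _fd_hessian(theta, total_fn):
    d = theta.size
    H = np.empty((d, d))
    h = _REL_STEP * np.maximum(1.0, np.abs(theta))
    f0 = total_fn(theta)
    for r in range(d):
        tp, tm = theta.copy(), theta.copy()
        tp[r] += h[r]
        tm[r] -= h[r]
        H[r, r] = (total_fn(tp) - 2.0 * f0 + total_fn(tm)) / h[r] ** 2
    for r in range(d):
        for s in range(r + 1, d):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[[r, s]] += [h[r], h[s]]
            tpm[r] += h[r]
            tpm[s] -= h[s]
            tmp[r] -= h[r]
            tmp[s] += h[s]
            tmm[[r, s]] -= [h[r], h[s]]
            H[r, s] = H[s, r] = (
                total_fn(tpp) - total_fn(tpm) - total_fn(tmp) + total_fn(tmm)
            ) / (4.0 * h[r] * h[s])
    return H


def sandwich_variance(fit: GLMMFit, augmented_data: ClusteredDataset,
                      spec: ModelSpec | None = None) -> np.ndarray:
    """A^{-1} B A^{-T} cluster-robust covariance on (beta, log tau).

    A is the finite-difference Hessian of the total augmented
    log-likelihood, B the outer-product sum of per-cluster scores.  The
    result is numerically symmetrized.  Not recommended for inference on
    the pseudo-observation estimator (biased); see the bootstrap module.
    """
    if not fit.converged:
        raise ValueError("sandwich variance requires a converged fit")
    if spec is None:
        spec = ModelSpec(covariates=augmented_data.covariate_names)
    theta, f = _per_cluster_fn(fit, augmented_data, spec)
    S = cluster_scores(fit, augmented_data, spec)
    B = S.T @ S
    A = _fd_hessian(theta, lambda th: float(np.sum(f(th))))
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular Hessian in sandwich variance (condition number {cond:.3g})"
        )
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv.T
    return 0.5 * (V + V.T)
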