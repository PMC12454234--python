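"""Maximum-likelihood random-intercept logistic mixed-effects model.

The marginal likelihood of each cluster integrates the conditional
Bernoulli likelihood over a scalar Gaussian random intercept,

    L_i(beta, tau) = int prod_j expit(x_ij'beta + eta)^y_ij
                     (1 - expit(x_ij'beta + eta))^(1 - y_ij)
                     phi(eta; 0, tau^2) d eta,

approximated by adaptive Gauss-Hermite quadrature (AGQ): nodes are centred
at each cluster's conditional mode and scaled by the curvature of the
integrand there, so a modest node count (default 25) is accurate even for
large clusters.  ``n_nodes=1`` is the Laplace approximation.

Optimization is over (beta, log tau) with an L-BFGS-B boundary check: when
the profiled optimum pushes tau to the lower boundary the model degenerates
to ordinary logistic regression, which is refitted exactly and flagged.

The gradient passed to the optimizer is the marginal score obtained from
Fisher's identity (posterior expectation of the complete-data score),
evaluated with the same quadrature rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermite

from .data import ClusteredDataset, ModelSpec

__all__ = [
    "GLMMFit",
    "SeparationError",
    "cluster_marginal_loglik",
    "fit_logistic_glmm",
    "fit_plain_logistic",
]

#: below this value tau is treated as sitting on the zero boundary
TAU_BOUNDARY = 1e-4
#: any |beta| component beyond this during optimization signals separation
BETA_CAP = 30.0

_LOG_2PI = np.log(2.0 * np.pi)


class SeparationError(RuntimeError):
    """Fixed-effect estimates diverged (complete or quasi-separation)."""


class ConvergenceError(RuntimeError):
    """Inner mode-finding or outer optimization failed."""


@dataclass
class GLMMFit:
    """Result of a (possibly degenerate) logistic GLMM fit.

    ``beta`` is on the log-odds scale of the data the model was fitted to;
    ``tau`` is the random-intercept standard deviation.  ``boundary_tau``
    is True when the variance component collapsed to zero, in which case
    ``loglik`` equals the plain-logistic log-likelihood.
    """

    beta: np.ndarray
    beta_names: list[str]
    tau: float
    loglik: float
    n_agq: int
    converged: bool
    iterations: int
    grad_norm: float
    boundary_tau: bool

    @property
    def theta(self) -> np.ndarray:
        """(beta, log tau); beta only when tau is on the boundary."""
        if self.boundary_tau:
            return np.asarray(self.beta, float)
        return np.append(self.beta, np.log(self.tau))

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])


# ---------------------------------------------------------------------------
# array-level machinery (shared by the public API and the bootstrap hot loop)
# ---------------------------------------------------------------------------


class _AGQProblem:
    """Precomputed structures for one dataset; rows sorted by cluster."""

    def __init__(self, y, X, cluster_idx, n_nodes, cluster_labels=None):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        cluster_idx = np.asarray(cluster_idx)
        order = np.argsort(cluster_idx, kind="stable")
        self.y = y[order]
        self.X = X[order]
        idx_sorted = cluster_idx[order]
        # re-code to dense 0..N-1 in sorted order
        change = np.r_[True, idx_sorted[1:] != idx_sorted[:-1]]
        self.idx = np.cumsum(change) - 1
        self.starts = np.flatnonzero(change)
        self.N = int(self.idx[-1]) + 1 if len(y) else 0
        self.cluster_labels = (
            cluster_labels[order][self.starts] if cluster_labels is not None else None
        )
        self.n, self.p = self.X.shape
        self.sgn = 2.0 * self.y - 1.0
        nodes, weights = roots_hermite(n_nodes)
        self.nodes = nodes
        self.logw_xx = np.log(weights) + nodes**2
        self.n_nodes = n_nodes
        self._u = np.zeros(self.N)  # warm-started conditional modes

    # -- conditional modes -------------------------------------------------

    def _modes(self, lin, tau2):
        """Per-cluster Newton for the mode of the integrand; vectorized."""
        u = self._u.copy()
        for _ in range(100):
            p = expit(lin + u[self.idx])
            g = np.bincount(self.idx, weights=self.y - p, minlength=self.N) - u / tau2
            h = -np.bincount(self.idx, weights=p * (1.0 - p), minlength=self.N) - 1.0 / tau2
            step = -g / h
            np.clip(step, -4.0, 4.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-11:
                break
        else:
            bad = int(np.argmax(np.abs(step)))
            label = self.cluster_labels[bad] if self.cluster_labels is not None else bad
            raise ConvergenceError(f"mode-finding did not converge for cluster {label!r}")
        self._u = u
        p = expit(lin + u[self.idx])
        h = -np.bincount(self.idx, weights=p * (1.0 - p), minlength=self.N) - 1.0 / tau2
        return u, np.sqrt(-1.0 / h)

    # -- marginal log-likelihood and score ---------------------------------

    def loglik_grad(self, theta, want_grad=True):
        """Total marginal log-likelihood and its gradient at (beta, log tau)."""
        beta, ltau = theta[: self.p], theta[self.p]
        if np.any(np.abs(beta) > BETA_CAP):
            raise SeparationError(
                "fixed-effect estimates diverged (|beta| > 30): the data are "
                "(quasi-)separated; penalized estimation is not provided"
            )
        tau = np.exp(ltau)
        tau2 = tau * tau
        lin = self.X @ beta
        if not np.all(np.isfinite(lin)):
            bad = int(np.flatnonzero(~np.isfinite(lin))[0])
            raise ValueError(f"non-finite linear predictor at row {bad}")
        u, sigma = self._modes(lin, tau2)
        # node locations per cluster (N x Q)
        eta = u[:, None] + np.sqrt(2.0) * sigma[:, None] * self.nodes[None, :]
        E = lin[:, None] + eta[self.idx, :]
        ll_rows = -np.logaddexp(0.0, -self.sgn[:, None] * E)  # log Bernoulli terms
        cs = np.add.reduceat(ll_rows, self.starts, axis=0)  # N x Q
        log_phi = -0.5 * _LOG_2PI - ltau - 0.5 * eta**2 / tau2
        log_integrand = self.logw_xx[None, :] + cs + log_phi
        m = log_integrand.max(axis=1, keepdims=True)
        t = np.exp(log_integrand - m)
        s = t.sum(axis=1)
        li = m[:, 0] + np.log(s) + 0.5 * np.log(2.0) + np.log(sigma)
        total = float(np.sum(li))
        if not want_grad:
            return total, None
        # Fisher's identity: score = posterior expectation of complete-data score
        lam = t / s[:, None]
        P = expit(E)
        resid = self.y - np.einsum("nq,nq->n", P, lam[self.idx, :])
        g_beta = self.X.T @ resid
        g_ltau = float(np.sum(lam * (eta**2 / tau2 - 1.0)))
        return total, np.append(g_beta, g_ltau)

    def per_cluster_loglik(self, beta, tau, n_nodes=None):
        """Vector of cluster marginal log-likelihoods (tau may be 0)."""
        if tau <= 0.0:
            lin = self.X @ np.asarray(beta, float)
            ll_rows = -np.logaddexp(0.0, -self.sgn * lin)
            return np.add.reduceat(ll_rows, self.starts)
        if n_nodes is not None and n_nodes != self.n_nodes:
            prob = _AGQProblem(self.y, self.X, self.idx, n_nodes)
            return prob.per_cluster_loglik(beta, tau)
        theta = np.append(np.asarray(beta, float), np.log(tau))
        beta_, ltau = theta[: self.p], theta[self.p]
        tau2 = tau * tau
        lin = self.X @ beta_
        u, sigma = self._modes(lin, tau2)
        eta = u[:, None] + np.sqrt(2.0) * sigma[:, None] * self.nodes[None, :]
        E = lin[:, None] + eta[self.idx, :]
        ll_rows = -np.logaddexp(0.0, -self.sgn[:, None] * E)
        cs = np.add.reduceat(ll_rows, self.starts, axis=0)
        log_phi = -0.5 * _LOG_2PI - ltau - 0.5 * eta**2 / tau2
        li = logsumexp(self.logw_xx[None, :] + cs + log_phi, axis=1)
        return li + 0.5 * np.log(2.0) + np.log(sigma)


def _irls_logistic(y, X, max_iter=100, tol=1e-12):
    """Plain logistic MLE by iteratively reweighted least squares."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(max_iter):
        lin = X @ beta
        mu = expit(lin)
        ll = float(np.sum(-np.logaddexp(0.0, -(2 * y - 1) * lin)))
        w = mu * (1.0 - mu)
        g = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix in logistic fit (separation or "
                "collinear covariates)"
            ) from exc
        # step-halving keeps the likelihood monotone
        for _ in range(30):
            cand = beta + step
            ll_new = float(np.sum(-np.logaddexp(0.0, -(2 * y - 1) * (X @ cand))))
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = cand
        if np.any(np.abs(beta) > BETA_CAP):
            raise SeparationError(
                "fixed-effect estimates diverged (|beta| > 30): the data are "
                "(quasi-)separated; penalized estimation is not provided"
            )
        if abs(ll_new - ll_old) < tol * (1.0 + abs(ll_new)):
            ll_old = ll_new
            break
        ll_old = ll_new
    lin = X @ beta
    grad = X.T @ (y - expit(lin))
    return beta, float(ll_old), it + 1, float(np.max(np.abs(grad)))


def _fit_arrays(y, X, cluster_idx, spec: ModelSpec, start=None,
                cluster_labels=None):
    """Core fitter on raw arrays; returns a GLMMFit."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    names = list(spec.term_names)
    if not (np.any(y == 1.0) and np.any(y == 0.0)):
        raise ValueError("both outcome values (0 and 1) must be present to fit")
    prob = _AGQProblem(y, X, cluster_idx, spec.n_nodes, cluster_labels=cluster_labels)

    # Plain-logistic fit doubles as starting value and as the basis of a
    # variance-component score test: d loglik / d tau^2 at tau -> 0 equals
    # (1/2) sum_i (g_i^2 + h_i) with g_i, h_i the first two derivatives of
    # cluster i's conditional log-likelihood in eta at 0.  When that slope
    # is non-positive the optimum sits on the tau = 0 boundary and the
    # plain MLE is the answer.
    beta_pl, ll_pl, its_pl, gnorm_pl = _irls_logistic(prob.y, prob.X)
    mu = expit(prob.X @ beta_pl)
    g_i = np.bincount(prob.idx, weights=prob.y - mu, minlength=prob.N)
    h_i = np.bincount(prob.idx, weights=mu * (1.0 - mu), minlength=prob.N)
    if float(np.sum(g_i * g_i - h_i)) <= 0.0:
        return GLMMFit(
            beta=beta_pl, beta_names=names, tau=0.0, loglik=ll_pl,
            n_agq=spec.n_nodes, converged=True, iterations=its_pl,
            grad_norm=gnorm_pl, boundary_tau=True,
        )

    if start is None:
        theta0 = np.append(beta_pl, np.log(0.1))
    else:
        theta0 = np.asarray(start, float).copy()
        if theta0[-1] < np.log(TAU_BOUNDARY):
            theta0[-1] = np.log(0.05)

    def nll(theta):
        ll, g = prob.loglik_grad(theta)
        return -ll, -g

    bounds = [(None, None)] * prob.p + [(np.log(TAU_BOUNDARY), 5.0)]
    res = minimize(
        nll, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": spec.max_iter, "ftol": spec.ftol, "gtol": spec.gtol},
    )
    theta = res.x
    ltau = theta[prob.p]
    # boundary check: at the bound, or so close that the plain-logistic
    # likelihood is not worse than the mixed-model one
    on_bound = ltau <= np.log(TAU_BOUNDARY) + 1e-9
    if not on_bound and np.exp(ltau) < 1e-3:
        on_bound = ll_pl >= -res.fun - 1e-7
    if on_bound:
        # variance component on the zero boundary: exact plain-logistic refit
        return GLMMFit(
            beta=beta_pl, beta_names=names, tau=0.0, loglik=ll_pl,
            n_agq=spec.n_nodes, converged=True,
            iterations=int(res.nit) + its_pl, grad_norm=gnorm_pl,
            boundary_tau=True,
        )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < spec.gtol
    return GLMMFit(
        beta=theta[: prob.p].copy(), beta_names=names, tau=float(np.exp(ltau)),
        loglik=float(-res.fun), n_agq=spec.n_nodes, converged=converged,
        iterations=int(res.nit), grad_norm=grad_norm, boundary_tau=False,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def cluster_marginal_loglik(cluster_rows: ClusteredDataset, beta, tau: float,
                            n_nodes: int = 25, spec: ModelSpec | None = None) -> float:
    """Marginal log-likelihood contribution of a single cluster.

    Integrates the conditional Bernoulli likelihood over the random
    intercept by AGQ with ``n_nodes`` nodes; ``tau=0`` returns the exact
    conditional log-likelihood at ``eta = 0``.
    """
    if len(cluster_rows) == 0:
        raise ValueError("cluster must be non-empty")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if spec is None:
        spec = ModelSpec(covariates=cluster_rows.covariate_names)
    y, X, codes = cluster_rows.design(spec)
    if cluster_rows.n_clusters != 1:
        raise ValueError("cluster_marginal_loglik expects rows of one cluster")
    beta = np.asarray(beta, float)
    with np.errstate(invalid="ignore"):
        lin = X @ beta
    if not np.all(np.isfinite(lin)):
        bad = int(np.flatnonzero(~np.isfinite(lin))[0])
        raise ValueError(f"non-finite linear predictor at row {bad}")
    prob = _AGQProblem(y, X, codes, n_nodes,
                       cluster_labels=cluster_rows.df["cluster"].to_numpy())
    return float(prob.per_cluster_loglik(beta, tau)[0])


def fit_logistic_glmm(data: ClusteredDataset, spec: ModelSpec | None = None,
                      start=None) -> GLMMFit:
    """ML fit of the random-intercept logistic GLMM by AGQ.

    Deterministic given the data, node count and optimizer options.  When
    the optimum lies on the tau = 0 boundary the returned fit is the exact
    ordinary logistic MLE with ``boundary_tau=True``.
    """
    if spec is None:
        spec = ModelSpec(covariates=data.covariate_names)
    if data.n_clusters < 1:
        raise ValueError("data must contain at least one cluster")
    y, X, codes = data.design(spec)
    return _fit_arrays(y, X, codes, spec, start=start,
                       cluster_labels=data.df["cluster"].to_numpy())


def fit_plain_logistic(data: ClusteredDataset, spec: ModelSpec | None = None) -> GLMMFit:
    """Ordinary (pooled) logistic regression, tau fixed at zero.

    Serves as the tau-boundary reference: its log-likelihood equals the
    GLMM marginal log-likelihood at tau = 0.
    """
    if spec is None:
        spec = ModelSpec(covariates=data.covariate_names)
    y, X, _ = data.design(spec)
    if not (np.any(y == 1.0) and np.any(y == 0.0)):
        raise ValueError("both outcome values (0 and 1) must be present to fit")
    beta, ll, its, gnorm = _irls_logistic(y, X)
    return GLMMFit(
        beta=beta, beta_names=list(spec.term_names), tau=0.0, loglik=ll,
        n_agq=spec.n_nodes, converged=gnorm < 1e-4, iterations=its,
        grad_norm=gnorm, boundary_tau=True,
    )
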