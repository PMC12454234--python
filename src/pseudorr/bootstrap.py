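"""Cluster nonparametric bootstrap for the pseudo-observation estimator.

Whole clusters are resampled with replacement and relabelled, preserving
the within-cluster correlation; each resample is augmented with
pseudo-observations and refitted.  Percentile confidence limits and
sign-count p-values are computed from the resulting coefficient samples.

Each replicate b draws from an independent RNG stream derived from
(seed, b), so results are identical whether replicates run serially or in
parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .augment import make_pseudo_observations  # noqa: F401  (re-export convenience)
from .data import ClusteredDataset, ModelSpec
from .glmm import ConvergenceError, SeparationError, _fit_arrays

__all__ = [
    "BootstrapResult",
    "cluster_resample",
    "bootstrap_estimates",
    "percentile_ci",
    "bootstrap_pvalue",
]


@dataclass
class BootstrapResult:
    """Bootstrap coefficient samples for one fitted model.

    ``samples`` has one row per successful resample fit (B - n_failed) on
    the log risk-ratio scale; ``tau_samples`` aligns with its rows.
    """

    samples: np.ndarray
    tau_samples: np.ndarray
    beta_names: list[str]
    B: int
    n_failed: int
    seed: int | None

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.beta_names.index(name)]


def _resample_cluster_ids(rng: np.random.Generator, n_clusters: int) -> np.ndarray:
    return rng.integers(0, n_clusters, size=n_clusters)


def cluster_resample(data: ClusteredDataset, rng: np.random.Generator) -> ClusteredDataset:
    """Draw N clusters with replacement and relabel them 1..N.

    A cluster drawn twice appears as two distinct relabelled clusters with
    all rows copied intact.
    """
    n_clust = data.n_clusters
    if n_clust < 2:
        raise ValueError("cluster bootstrap requires at least 2 clusters")
    codes, labels = pd.factorize(data.df["cluster"], sort=False)
    draw = _resample_cluster_ids(rng, n_clust)
    parts = []
    for new_label, code in enumerate(draw, start=1):
        rows = data.df[codes == code].copy()
        rows["cluster"] = new_label
        parts.append(rows)
    return ClusteredDataset(pd.concat(parts, ignore_index=True), validate=False)


def _one_replicate(y, X, codes, row_lists, sizes, spec, start, ss):
    """Resample -> drop missing -> augment -> fit, all on arrays."""
    rng = np.random.Generator(np.random.PCG64(ss))
    draw = _resample_cluster_ids(rng, len(row_lists))
    rows = np.concatenate([row_lists[c] for c in draw])
    new_codes = np.repeat(np.arange(len(draw)), sizes[draw])
    yb, Xb = y[rows], X[rows]
    keep = ~np.isnan(yb)
    yb, Xb, new_codes = yb[keep], Xb[keep], new_codes[keep]
    ev = yb == 1.0
    yb = np.concatenate([yb, np.zeros(ev.sum())])
    Xb = np.vstack([Xb, Xb[ev]])
    new_codes = np.concatenate([new_codes, new_codes[ev]])
    try:
        fit = _fit_arrays(yb, Xb, new_codes, spec, start=start)
        if not fit.converged:
            return None
        return fit.beta, fit.tau
    except (SeparationError, ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None


def bootstrap_estimates(data: ClusteredDataset, spec: ModelSpec, B: int = 1000,
                        seed: int | None = None, n_jobs: int = 1,
                        start=None) -> BootstrapResult:
    """Cluster bootstrap of the pseudo-observation GLMM estimates.

    ``data`` is the original (un-augmented) dataset; rows with missing
    outcomes are carried into the resamples and dropped before each fit.
    Failed resample fits are dropped and counted, not redrawn.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = data.df["y"].to_numpy(float)
    cols = [np.ones(len(y))] if spec.intercept else []
    cols += [data.df[c].to_numpy(float) for c in spec.covariates]
    X = np.column_stack(cols)
    codes, _ = pd.factorize(data.df["cluster"], sort=False)
    order = np.argsort(codes, kind="stable")
    row_lists = np.split(order, np.cumsum(np.bincount(codes))[:-1])
    sizes = np.array([len(r) for r in row_lists])

    seeds = np.random.SeedSequence(seed).spawn(B)
    if n_jobs == 1:
        results = [_one_replicate(y, X, codes, row_lists, sizes, spec, start, ss)
                   for ss in seeds]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(y, X, codes, row_lists, sizes, spec, start, ss)
            for ss in seeds
        )
    ok = [r for r in results if r is not None]
    n_failed = B - len(ok)
    if not ok:
        raise RuntimeError(f"all {B} bootstrap fits failed")
    if n_failed > 0.05 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap fits failed; intervals may be unreliable",
            stacklevel=2,
        )
    samples = np.array([b for b, _ in ok])
    taus = np.array([t for _, t in ok])
    return BootstrapResult(
        samples=samples, tau_samples=taus, beta_names=list(spec.term_names),
        B=B, n_failed=n_failed, seed=seed,
    )


def percentile_ci(samples, level: float = 0.95):
    """Percentile bootstrap interval with the inclusive linear-interpolation
    (type 7) quantile definition."""
    samples = np.asarray(samples, float)
    samples = samples[np.isfinite(samples)]
    if samples.size < 2:
        raise ValueError("percentile_ci requires at least 2 finite samples")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def bootstrap_pvalue(samples, null_value: float = 0.0) -> float:
    """Two-sided add-one sign-count bootstrap p-value.

    p = 2 * min{(1 + #{b* <= null}) / (B+1), (1 + #{b* >= null}) / (B+1)},
    capped at 1; exact at the boundary and consistent with the percentile
    interval.
    """
    samples = np.asarray(samples, float)
    if samples.size < 2:
        raise ValueError("bootstrap_pvalue requires at least 2 samples")
    B = samples.size
    le = np.sum(samples <= null_value)
    ge = np.sum(samples >= null_value)
    p = 2.0 * min((1 + le) / (B + 1), (1 + ge) / (B + 1))
    return float(min(p, 1.0))
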