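import numpy as np
import pytest

from pseudorr.data import ClusteredDataset, ModelSpec

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def two_group_dataset(n0=100, m0=20, n1=100, m1=40, clusters_per_group=1):
    """Two-arm dataset with exact event counts (risks m1/n1 vs m0/n0)."""
    rows_y, rows_g, rows_c = [], [], []
    for g, (n, m) in enumerate([(n0, m0), (n1, m1)]):
        rows_y += [1.0] * m + [0.0] * (n - m)
        rows_g += [float(g)] * n
        # round-robin assignment keeps per-cluster event rates homogeneous
        rows_c += [f"g{g}c{k % clusters_per_group}" for k in range(n)]
    return ClusteredDataset.from_arrays(rows_c, rows_y, {"group": rows_g})


@pytest.fixture
def small_cluster():
    """One 2-row cluster used by quadrature-oracle checks."""
    return ClusteredDataset.from_arrays(
        [1, 1], [1.0, 0.0], {"x": [0.3, -0.1]})


@pytest.fixture
def slope_spec():
    return ModelSpec(covariates=["x"], intercept=False)


@pytest.fixture
def glmm_sim():
    """Seeded logistic-GLMM draw: (dataset, true beta, true tau)."""

    def make(N=200, n_per=4, beta=(-1.0, 0.5), tau=1.0, seed=1):
        from scipy.special import expit

        rng = np.random.default_rng(seed)
        cl = np.repeat(np.arange(N), n_per)
        x = rng.normal(size=N * n_per)
        eta = rng.normal(0.0, tau, N)[cl]
        p = expit(beta[0] + beta[1] * x + eta)
        y = (rng.random(N * n_per) < p).astype(float)
        return ClusteredDataset.from_arrays(cl, y, {"x": x})

    return make
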