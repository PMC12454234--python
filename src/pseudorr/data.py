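"""Long-format clustered binary outcome data.

A :class:`ClusteredDataset` holds one row per observation unit: a cluster
label (participant, centre, district, ...), a binary outcome ``y`` (0/1, or
missing), any number of numeric covariate columns, and an ``is_pseudo`` flag
marking augmented zero-outcome copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("cluster", "y", "is_pseudo")

__all__ = ["ClusteredDataset", "ModelSpec", "read_csv", "RESERVED_COLUMNS"]


class DataError(ValueError):
    """Raised when a dataset violates the clustered-data contract."""


@dataclass
class ModelSpec:
    """Fixed-effect structure and fitting options for the logistic GLMM.

    Parameters
    ----------
    covariates
        Names of covariate columns entering the linear predictor.
    intercept
        Include an always-on intercept column (default).  Opting out must
        be explicit.
    n_nodes
        Adaptive Gauss-Hermite node count; 1 gives the Laplace
        approximation.
    """

    covariates: list[str] = field(default_factory=list)
    intercept: bool = True
    n_nodes: int = 25
    gtol: float = 1e-6
    ftol: float = 1e-10
    max_iter: int = 500

    @property
    def term_names(self) -> list[str]:
        names = ["intercept"] if self.intercept else []
        return names + list(self.covariates)


class ClusteredDataset:
    """Long-format table of clustered binary observations.

    Wraps a :class:`pandas.DataFrame` with columns ``cluster``, ``y``,
    ``is_pseudo`` plus covariates.  ``y`` may contain NaN for missing
    outcomes; every non-missing value must be exactly 0 or 1.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        if "cluster" not in df.columns or "y" not in df.columns:
            raise DataError("dataset requires 'cluster' and 'y' columns")
        if "is_pseudo" not in df.columns:
            df["is_pseudo"] = False
        df["is_pseudo"] = df["is_pseudo"].astype(bool)
        df["y"] = pd.to_numeric(df["y"], errors="coerce").astype(float)
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_arrays(cls, cluster, y, covariates: dict | None = None,
                    is_pseudo=None) -> "ClusteredDataset":
        data = {"cluster": cluster, "y": y}
        if covariates:
            data.update(covariates)
        if is_pseudo is not None:
            data["is_pseudo"] = is_pseudo
        return cls(pd.DataFrame(data))

    @classmethod
    def from_csv(cls, path) -> "ClusteredDataset":
        """Read long-format CSV with required columns ``cluster`` and ``y``.

        Empty cells in ``y`` are missing outcomes; all remaining columns
        except ``is_pseudo`` are treated as covariates.
        """
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        """Write the same dialect back, always including ``is_pseudo``."""
        cols = ["cluster", "y"] + self.covariate_names + ["is_pseudo"]
        self.df[cols].to_csv(path, index=False)

    # -- properties --------------------------------------------------------

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_COLUMNS]

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def n_clusters(self) -> int:
        return self.df["cluster"].nunique()

    @property
    def n_events(self) -> int:
        """Total observed events M (missing outcomes excluded)."""
        return int((self.df["y"] == 1).sum())

    @property
    def has_missing_outcomes(self) -> bool:
        return bool(self.df["y"].isna().any())

    @property
    def has_pseudo(self) -> bool:
        return bool(self.df["is_pseudo"].any())

    # -- operations --------------------------------------------------------

    def validate(self) -> None:
        y = self.df["y"]
        obs = y.dropna()
        if not obs.isin([0.0, 1.0]).all():
            bad = obs[~obs.isin([0.0, 1.0])].index[0]
            raise DataError(f"outcome must be 0/1 or missing; row {bad} is {obs[bad]!r}")
        names = self.covariate_names
        if len(set(names)) != len(names):
            raise DataError("duplicate covariate names")
        for c in names:
            col = pd.to_numeric(self.df[c], errors="coerce")
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise DataError(
                    f"covariate {c!r} is missing or non-numeric at row {row}; "
                    "rows with missing covariates are not supported"
                )
            if not np.isfinite(col.to_numpy()).all():
                raise DataError(f"covariate {c!r} contains non-finite values")

    def drop_missing_outcomes(self) -> "ClusteredDataset":
        """Direct-likelihood handling of dropout: keep observed rows only."""
        out = ClusteredDataset(self.df[self.df["y"].notna()].reset_index(drop=True),
                               validate=False)
        return out

    def design(self, spec: ModelSpec):
        """Return (y, X, cluster_codes) arrays for fitting.

        Rows must have no missing outcomes; covariates named in ``spec``
        must exist.
        """
        if self.has_missing_outcomes:
            raise DataError("rows with missing outcome must be dropped before fitting")
        missing = [c for c in spec.covariates if c not in self.df.columns]
        if missing:
            raise DataError(f"covariates not in dataset: {missing}")
        y = self.df["y"].to_numpy(float)
        cols = []
        if spec.intercept:
            cols.append(np.ones(len(y)))
        for c in spec.covariates:
            cols.append(self.df[c].to_numpy(float))
        X = np.column_stack(cols) if cols else np.empty((len(y), 0))
        codes, _ = pd.factorize(self.df["cluster"], sort=False)
        return y, X, codes

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (f"ClusteredDataset({self.n_rows} rows, {self.n_clusters} clusters, "
                f"{self.n_events} events, covariates={self.covariate_names})")


def read_csv(path) -> ClusteredDataset:
    return ClusteredDataset.from_csv(path)
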