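"""Pseudo-observation augmentation.

For every observed event (y = 1) a copy of the row with y = 0, the same
cluster label and the same covariates is appended.  Fitting the ordinary
logistic mixed-effects model to the augmented data turns fitted odds into
fitted risks: per covariate stratum the augmented odds are m/n, the
original risk, so exponentiated coefficients become risk ratios.
"""

from __future__ import annotations

import pandas as pd

from .data import ClusteredDataset, DataError

__all__ = ["make_pseudo_observations", "strip_pseudo_observations"]


def make_pseudo_observations(data: ClusteredDataset) -> ClusteredDataset:
    """Append a zero-outcome pseudo copy of every event row.

    The output has n + M rows (M = number of events), the event count is
    unchanged, and every added row carries ``is_pseudo=True``.  Within each
    cluster the copies follow the original rows; their order carries no
    information.
    """
    if data.has_pseudo:
        raise DataError(
            "dataset already contains pseudo-observations; augmenting twice "
            "would corrupt the risk-ratio estimand"
        )
    if data.has_missing_outcomes:
        raise DataError("drop rows with missing outcomes before augmentation")
    df = data.df
    events = df[df["y"] == 1.0].copy()
    events["y"] = 0.0
    events["is_pseudo"] = True
    # copies are appended after all originals; their running index within a
    # cluster is anonymous, and the fit is invariant to row order anyway
    out = pd.concat([df, events], ignore_index=True)
    return ClusteredDataset(out, validate=False)


def strip_pseudo_observations(data: ClusteredDataset) -> ClusteredDataset:
    """Inverse of :func:`make_pseudo_observations`: drop flagged rows."""
    df = data.df[~data.df["is_pseudo"]].reset_index(drop=True)
    return ClusteredDataset(df, validate=False)
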