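"""k-nearest-neighbour imputation of missing protein levels.

Classifier fitting needs a complete matrix, so missing cells (run-level
undersampling) are filled just before that step: for a missing level of
protein g in sample j, find the k proteins whose observed profiles are
closest to g's (Euclidean distance over co-observed samples, scaled by
the co-observation count so sparse overlaps are not favoured), and impute
the inverse-distance-weighted average of their values in sample j.
Neighbours missing at j are skipped and the next nearest used, keeping k
contributors whenever possible.  Rows missing more than a configurable
fraction of their entries fall back to the row mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .matrix import QuantMatrix

_EPS = 1e-12


@dataclass
class ImputeConfig:
    k: int = 10
    max_missing_frac_row: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.max_missing_frac_row <= 1):
            raise ValueError("max_missing_frac_row must lie in (0, 1]")


def knn_impute(
    matrix: QuantMatrix, cfg: ImputeConfig | None = None
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Impute all missing cells; returns (complete matrix, imputed-cell mask).

    Observed cells are never altered.  Ties in neighbour distance are
    broken by row order for determinism.  A column with no observed value
    at all cannot be imputed and raises.
    """
    cfg = cfg or ImputeConfig()
    vals = matrix.values
    X = vals.to_numpy(dtype=float, copy=True)
    obs = ~np.isnan(X)
    n_rows, n_cols = X.shape

    empty_cols = np.where(~obs.any(axis=0))[0]
    if empty_cols.size:
        names = [vals.columns[i] for i in empty_cols]
        raise ValueError(f"columns with zero observed values cannot be imputed: {names}")
    if not obs.any(axis=1).all():
        raise ValueError("every row must have at least one observed value")

    imputed_mask = pd.DataFrame(~obs, index=vals.index, columns=vals.columns)
    if obs.all():
        return QuantMatrix(vals.copy(), scale=matrix.scale), imputed_mask

    row_means = np.nanmean(X, axis=1)
    missing_frac = 1.0 - obs.mean(axis=1)
    fallback_rows = missing_frac > cfg.max_missing_frac_row

    # distance over co-observed columns, normalized by co-observation count
    # (nan_euclidean scales by n_cols / n_present; the constant sqrt(n_cols)
    # factor cancels in the normalized inverse-distance weights)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = nan_euclidean_distances(X)
    np.fill_diagonal(dist, np.inf)
    dist[np.isnan(dist)] = np.inf  # no co-observed columns

    out = X.copy()
    todo_rows = np.where((~obs.all(axis=1)))[0]
    # stable neighbor order: distance then row index
    order_cache: dict[int, np.ndarray] = {}
    for g in todo_rows:
        if fallback_rows[g]:
            out[g, ~obs[g]] = row_means[g]
            continue
        if g not in order_cache:
            order_cache[g] = np.lexsort((np.arange(n_rows), dist[g]))
        order = order_cache[g]
        for j in np.where(~obs[g])[0]:
            neigh_vals = []
            neigh_w = []
            for cand in order:
                if not obs[cand, j] or not np.isfinite(dist[g, cand]):
                    continue  # skip-and-extend: take the next nearest instead
                neigh_vals.append(X[cand, j])
                neigh_w.append(1.0 / max(dist[g, cand], _EPS))
                if len(neigh_vals) == cfg.k:
                    break
            if neigh_vals:
                w = np.asarray(neigh_w)
                out[g, j] = float(np.dot(w, neigh_vals) / w.sum())
            else:
                out[g, j] = row_means[g]

    complete = QuantMatrix(
        pd.DataFrame(out, index=vals.index, columns=vals.columns), scale=matrix.scale
    )
    return complete, imputed_mask


def column_mean_impute(matrix: QuantMatrix) -> QuantMatrix:
    """Baseline: fill each missing cell with its column (sample) mean."""
    vals = matrix.values
    filled = vals.fillna(vals.mean(axis=0))
    if filled.isna().any().any():
        raise ValueError("columns with zero observed values cannot be imputed")
    return QuantMatrix(filled, scale=matrix.scale)
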