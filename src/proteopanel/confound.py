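"""Confounder checks: global permutation ANCOVA and score correlations.

A panel that separates cases from controls may do so through a clinical
covariate (drug dose, weight, blood pressure ...) rather than disease.
Two complementary checks are provided:

* a global multivariate ANCOVA over the panel — per protein, the full
  model (intercept + covariate + group) is compared with the reduced
  model (intercept + covariate); the statistic sums the extra residual
  sums of squares across panel proteins, normalized by the summed full
  residual, and significance comes from permutation so the test stays
  honest at n ~ 20;
* the Pearson correlation of each covariate with the classifier score,
  flagged at the |r| >= 0.5 screening threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import QuantMatrix


@dataclass
class AncovaResult:
    """Permutation ANCOVA outcome for one covariate (mirrors a report row)."""

    covariate: str
    statistic: float
    p_value: float
    n_permutations: int
    exact: bool
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    n_samples: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-row residual sum of squares of Y (G x n) on design X (n x p)."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    return (resid**2).sum(axis=0)


def _statistic(Y: np.ndarray, X_red: np.ndarray, g: np.ndarray) -> float:
    X_full = np.column_stack([X_red, g])
    rss_red = _rss(Y, X_red)
    rss_full = _rss(Y, X_full)
    denom = rss_full.sum()
    if denom <= 0:
        return np.inf
    return float((rss_red - rss_full).sum() / denom)


def global_ancova(
    panel_matrix: QuantMatrix,
    group: Mapping[str, str] | pd.Series,
    covariate: Mapping[str, float] | pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
    case: str = "AR",
    control: str = "NR",
    name: str | None = None,
) -> AncovaResult:
    """Covariate-adjusted global group test over the panel, by permutation.

    When the number of distinct case/control label arrangements is at
    most ``n_perm`` the null distribution is enumerated exactly;
    otherwise ``n_perm`` Freedman-Lane permutations are drawn (reduced-
    model residual columns permuted, statistic recomputed).  The add-one
    convention keeps Monte-Carlo p-values strictly positive, with
    resolution 1/(n_perm + 1).  Samples with a missing covariate are
    dropped with a warning; a constant covariate reduces to the
    unadjusted test, also with a warning.
    """
    group = pd.Series(dict(group)) if not isinstance(group, pd.Series) else group
    covariate = (
        pd.Series(dict(covariate)) if not isinstance(covariate, pd.Series) else covariate
    )
    samples = [s for s in panel_matrix.col_ids if s in group.index]
    cov = covariate.reindex(samples)
    if cov.isna().any():
        dropped = cov.index[cov.isna()].tolist()
        warnings.warn(f"dropping samples with missing covariate: {dropped}", stacklevel=2)
        samples = [s for s in samples if s not in set(dropped)]
        cov = cov.loc[samples]

    Y = panel_matrix.values[samples].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("panel matrix must be complete for the ANCOVA (impute first)")
    # standardize protein rows so no single protein's scale dominates the
    # pooled statistic (also makes it invariant to per-row affine rescaling)
    sd = Y.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Y = (Y - Y.mean(axis=1, keepdims=True)) / sd
    g = (group.reindex(samples) == case).to_numpy(dtype=float)
    n = len(samples)
    n_case = int(g.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("both groups must be present")

    c = cov.to_numpy(dtype=float)
    adjusted = True
    if np.ptp(c) == 0:
        warnings.warn("constant covariate: reducing to the unadjusted group test", stacklevel=2)
        adjusted = False
    X_red = np.column_stack([np.ones(n), c]) if adjusted else np.ones((n, 1))

    obs = _statistic(Y, X_red, g)

    n_arrangements = comb(n, n_case)
    if n_arrangements <= n_perm:
        # exact: enumerate all distinct case/control arrangements
        count = 0
        for case_idx in combinations(range(n), n_case):
            g_perm = np.zeros(n)
            g_perm[list(case_idx)] = 1.0
            if _statistic(Y, X_red, g_perm) >= obs - 1e-12:
                count += 1
        p = count / n_arrangements
        eff_perm, exact = n_arrangements, True
    else:
        # Freedman-Lane: permute reduced-model residual columns; the
        # statistic on permuted residuals equals the Freedman-Lane
        # statistic because RSS_red and RSS_full are unchanged by
        # removing the reduced-model fit.
        beta, *_ = np.linalg.lstsq(X_red, Y.T, rcond=None)
        R = (Y.T - X_red @ beta).T  # G x n residual matrix
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _statistic(R[:, perm], X_red, g) >= obs - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
        eff_perm, exact = n_perm, False

    cvals_case = cov.to_numpy(dtype=float)[g == 1]
    cvals_ctrl = cov.to_numpy(dtype=float)[g == 0]
    return AncovaResult(
        covariate=name if name is not None else getattr(covariate, "name", None) or "covariate",
        statistic=obs,
        p_value=float(p),
        n_permutations=eff_perm,
        exact=exact,
        case_mean=float(np.mean(cvals_case)),
        case_sd=float(np.std(cvals_case, ddof=1)) if len(cvals_case) > 1 else float("nan"),
        control_mean=float(np.mean(cvals_ctrl)),
        control_sd=float(np.std(cvals_ctrl, ddof=1)) if len(cvals_ctrl) > 1 else float("nan"),
        n_samples=n,
    )


def confounder_table(
    panel_matrix: QuantMatrix,
    group: pd.Series,
    confounders: pd.DataFrame,
    scores: pd.Series | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    case: str = "AR",
    control: str = "NR",
) -> pd.DataFrame:
    """One ANCOVA per confounder (tested singly) plus score correlations.

    Reproduces the standard report layout: covariate, adjusted global
    p-value, correlation with the classifier score, case and control
    mean (SD).
    """
    rows = []
    corr = (
        score_confounder_correlations(scores, confounders) if scores is not None else None
    )
    for i, col in enumerate(confounders.columns):
        res = global_ancova(
            panel_matrix, group, confounders[col], n_perm=n_perm, seed=seed + i,
            case=case, control=control, name=col,
        )
        row = res.to_dict()
        if corr is not None and col in corr.index:
            row["correlation_with_score"] = corr.loc[col, "r"]
            row["high_correlation"] = corr.loc[col, "flag"]
        rows.append(row)
    return pd.DataFrame(rows)


def score_confounder_correlations(
    scores: Mapping[str, float] | pd.Series, confounders: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Pearson r of the classifier score with each confounder.

    Covariates with |r| >= threshold (default 0.5) are flagged for
    review; a zero-variance covariate has undefined r, reported as NaN
    and unflagged.  Requires >= 3 paired observations per covariate.
    """
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    rows = {}
    for col in confounders.columns:
        pair = pd.concat([scores, confounders[col]], axis=1, join="inner").dropna()
        if len(pair) < 3:
            raise ValueError(f"confounder {col!r}: need >= 3 paired observations")
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows[col] = {"r": r, "n": len(pair), "flag": bool(abs(r) >= threshold) if r == r else False}
    return pd.DataFrame.from_dict(rows, orient="index")
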