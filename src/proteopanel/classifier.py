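"""LDA panel classifier: centered score, cross-validation, panels, calibration.

A biomarker panel is turned into a single *classifier score* by linear
discriminant analysis: w = S_pooled^{-1} (mu_case - mu_control), with the
score centered at the decision boundary, score(x) = w.x - c, so that a
positive score classifies a sample as a case (rejection) and the boundary
sits exactly where the LDA posterior probability of "case" is 0.5 under
the training priors.  Performance of nested panels is estimated by
stratified k-fold cross-validation with shared fold assignments, so that
differences between panels reflect the panel alone.

Panel membership and model form can be locked for external validation;
migrating to a new assay then refits only (w, c) on the new platform
("calibration") while the panel stays fixed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .matrix import QuantMatrix


@dataclass
class PanelClassifier:
    """Ordered protein panel with LDA weights and a centering offset.

    score(x) = w.x - c; score > 0 predicts the case class.  ``priors``
    are the training class proportions (case, control) used to place the
    probability-0.5 boundary at score 0.
    """

    panel: list[str]
    weights: np.ndarray
    offset: float
    priors: tuple[float, float]
    case: str = "AR"
    control: str = "NR"
    locked: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.panel) != self.weights.size:
            raise ValueError("panel and weights must have the same length")

    def lock(self) -> "PanelClassifier":
        return replace(self, locked=True)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "panel": list(self.panel),
            "weights": self.weights.tolist(),
            "offset": self.offset,
            "priors": list(self.priors),
            "case": self.case,
            "control": self.control,
            "locked": self.locked,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PanelClassifier":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            panel=payload["panel"],
            weights=np.asarray(payload["weights"]),
            offset=payload["offset"],
            priors=tuple(payload["priors"]),
            case=payload["case"],
            control=payload["control"],
            locked=payload["locked"],
        )


@dataclass
class CVReport:
    """Out-of-fold performance of one panel under stratified k-fold CV."""

    panel: list[str]
    sensitivity: float
    specificity: float
    auc: float
    fold_assignments: pd.Series  # sample_id -> fold index
    scores: pd.DataFrame  # sample, score, probability, predicted, true

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _design(matrix: QuantMatrix | pd.DataFrame, panel: Sequence[str] | None):
    """samples x panel design matrix from a feature x sample QuantMatrix."""
    vals = matrix.values if isinstance(matrix, QuantMatrix) else matrix
    if panel is None:
        panel = list(vals.index)
    missing = [p for p in panel if p not in vals.index]
    if missing:
        raise KeyError(f"panel features absent from matrix: {missing}")
    X = vals.loc[list(panel)].T
    if X.isna().any().any():
        raise ValueError("matrix must be complete on the panel (impute first)")
    return X, list(panel)


def fit_lda(
    matrix: QuantMatrix | pd.DataFrame,
    y: Mapping[str, str] | pd.Series,
    panel: Sequence[str] | None = None,
    case: str = "AR",
    control: str = "NR",
    priors: tuple[float, float] | None = None,
    ridge: bool = True,
) -> PanelClassifier:
    """Fit the two-class LDA panel classifier in closed form.

    w = S_pooled^{-1} (mu_case - mu_control) with the pooled within-class
    covariance (maximum-likelihood normalization, so replicating the
    data leaves the fit unchanged); the offset places score 0 at LDA
    posterior probability 0.5 under the training priors (empirical class
    proportions unless ``priors`` is given).  A singular pooled
    covariance falls back to ridge regularization S + lambda I with
    lambda = 1e-6 tr(S)/p when ``ridge`` is enabled.
    """
    X, panel = _design(matrix, panel)
    y = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    y = y.reindex(X.index)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    mask_case = (y == case).to_numpy()
    mask_control = (y == control).to_numpy()
    n1, n0 = int(mask_case.sum()), int(mask_control.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples per class")

    A = X.to_numpy(dtype=float)
    mu1 = A[mask_case].mean(axis=0)
    mu0 = A[mask_control].mean(axis=0)
    d1 = A[mask_case] - mu1
    d0_ = A[mask_control] - mu0
    n = n1 + n0
    S = (d1.T @ d1 + d0_.T @ d0_) / n

    p = len(panel)
    try:
        cond = np.linalg.cond(S)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        if not ridge:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular; enable ridge=True or shrink the panel"
            )
        lam = 1e-6 * np.trace(S) / p
        if lam <= 0:
            lam = 1e-12
        warnings.warn(f"singular pooled covariance: ridge lambda={lam:.3e} applied", stacklevel=2)
        S = S + lam * np.eye(p)

    w = np.linalg.solve(S, mu1 - mu0)
    if priors is None:
        priors = (n1 / n, n0 / n)
    pi1, pi0 = priors
    c = float(w @ (mu1 + mu0) / 2 - np.log(pi1 / pi0))
    return PanelClassifier(
        panel=panel, weights=w, offset=c, priors=(pi1, pi0), case=case, control=control
    )


def score_samples(model: PanelClassifier, matrix: QuantMatrix | pd.DataFrame) -> pd.DataFrame:
    """Signed scores, case probabilities and predicted labels per sample.

    score = w.x - c is the LDA log-odds of the case class, so the
    probability is its logistic transform and probability > 0.5 is
    exactly score > 0.
    """
    X, _ = _design(matrix, model.panel)
    scores = X.to_numpy(dtype=float) @ model.weights - model.offset
    prob = 1.0 / (1.0 + np.exp(-scores))
    pred = np.where(scores > 0, model.case, model.control)
    return pd.DataFrame(
        {"score": scores, "probability": prob, "predicted": pred}, index=X.index
    )


def roc_auc(scores: Sequence[float], y: Sequence, case: str = "AR") -> float:
    """AUC as rank concordance: P(score_case > score_control) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    is_case = y == case
    n1 = int(is_case.sum())
    n0 = int((~is_case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores)  # midranks handle ties
    return float((ranks[is_case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _make_folds(y: pd.Series, k: int, seed: int, case: str) -> pd.Series:
    """Class-stratified fold assignment, deterministic given seed.

    Fold sizes differ by <= 1 per class.  If any training split would
    contain a single class, the folds are re-drawn with a warning.
    """
    y_arr = (y == case).astype(int).to_numpy()
    for attempt in range(20):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        assign = pd.Series(index=y.index, dtype=int)
        ok = True
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y_arr)):
            assign.iloc[test_idx] = fold
            if len(np.unique(y_arr[train_idx])) < 2:
                ok = False
        if ok:
            if attempt > 0:
                warnings.warn(f"folds re-drawn {attempt} time(s) to keep both classes in training")
            return assign
    raise ValueError("could not construct folds with both classes in every training split")


def stratified_kfold_cv(
    matrix: QuantMatrix | pd.DataFrame,
    y: Mapping[str, str] | pd.Series,
    panel: Sequence[str] | None = None,
    k: int = 6,
    seed: int = 0,
    case: str = "AR",
    control: str = "NR",
    folds: pd.Series | None = None,
) -> CVReport:
    """Stratified k-fold CV of the LDA panel classifier.

    The model is refit on each training split; out-of-fold scores are
    pooled into a single confusion matrix (sensitivity/specificity at
    probability 0.5, i.e. score 0) and a single AUC.  Pass ``folds`` to
    reuse fold assignments across panels.
    """
    X, panel = _design(matrix, panel)
    y = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    y = y.reindex(X.index)
    if folds is None:
        folds = _make_folds(y, k, seed, case)
    folds = folds.reindex(X.index)

    rows = []
    for fold in sorted(folds.unique()):
        test_ids = folds.index[folds == fold]
        train_ids = folds.index[folds != fold]
        model = fit_lda(
            X.loc[train_ids].T, y.loc[train_ids], panel=panel, case=case, control=control
        )
        scored = score_samples(model, X.loc[test_ids].T)
        scored["true"] = y.loc[test_ids]
        scored["fold"] = fold
        rows.append(scored)
    scored = pd.concat(rows).loc[X.index]

    tp = int(((scored["predicted"] == case) & (scored["true"] == case)).sum())
    fn = int(((scored["predicted"] != case) & (scored["true"] == case)).sum())
    tn = int(((scored["predicted"] != case) & (scored["true"] != case)).sum())
    fp = int(((scored["predicted"] == case) & (scored["true"] != case)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = roc_auc(scored["score"], scored["true"], case=case)
    return CVReport(
        panel=panel,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        fold_assignments=folds,
        scores=scored,
    )


def incremental_panels(
    matrix: QuantMatrix | pd.DataFrame,
    y: Mapping[str, str] | pd.Series,
    ordered_panel: Sequence[str],
    k: int = 6,
    seed: int = 0,
    case: str = "AR",
    control: str = "NR",
) -> list[CVReport]:
    """CV reports for the nested panels [p1], [p1,p2], ... with shared folds.

    Sequentially adding corroborated markers measures each marker's
    complementary contribution: identical fold assignments guarantee that
    differences between reports reflect the panel only.
    """
    if not ordered_panel:
        raise ValueError("ordered_panel must be non-empty")
    X, _ = _design(matrix, list(ordered_panel))
    y = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    y = y.reindex(X.index)
    folds = _make_folds(y, k, seed, case)
    return [
        stratified_kfold_cv(
            matrix, y, panel=list(ordered_panel[: i + 1]), k=k, seed=seed,
            case=case, control=control, folds=folds,
        )
        for i in range(len(ordered_panel))
    ]


def longitudinal_score_summary(
    model: PanelClassifier,
    matrix: QuantMatrix | pd.DataFrame,
    manifest,
    case: str = "AR",
    control: str = "NR",
) -> dict:
    """Classifier-score trajectories by class and week, plus transitions.

    Returns per (class, week) mean score, standard error (absent for
    single-sample cells) and count; a transition table averaging, per
    case patient, the first consecutive run of AR time points and the
    flanking NR points; and a two-sided t-test comparing case scores at
    rejection points with control-patient scores at the same weeks.
    """
    tab = manifest.table.set_index("sample_id")
    scored = score_samples(model, matrix)
    common = scored.index.intersection(tab.index)
    scored = scored.loc[common]
    info = tab.loc[common]

    df = pd.DataFrame(
        {"score": scored["score"], "class": info["class"], "week": info["week"],
         "patient": info["patient_id"]}
    )
    by_week = (
        df.groupby(["class", "week"])["score"]
        .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
             n="count")
        .reset_index()
    )

    # transition summary: per patient with an AR episode
    pre, rej, post, rejection_weeks = [], [], [], set()
    for patient, grp in df.groupby("patient"):
        grp = grp.sort_values("week")
        classes = grp["class"].tolist()
        if case not in classes:
            continue
        first = classes.index(case)
        last = first
        while last + 1 < len(classes) and classes[last + 1] == case:
            last += 1
        block = grp.iloc[first : last + 1]
        rej.append(block["score"].mean())
        rejection_weeks.update(block["week"].tolist())
        before = grp.iloc[:first]
        before = before[before["class"] == control]
        after = grp.iloc[last + 1 :]
        after = after[after["class"] == control]
        if len(before):
            pre.append(before["score"].mean())
        if len(after):
            post.append(after["score"].mean())

    def _summ(vals: list) -> dict:
        if not vals:
            return {"mean": np.nan, "se": np.nan, "n": 0}
        arr = np.asarray(vals, dtype=float)
        se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
        return {"mean": float(arr.mean()), "se": float(se) if se == se else np.nan, "n": len(arr)}

    transition = pd.DataFrame(
        {"pre_rejection": _summ(pre), "rejection": _summ(rej), "post_rejection": _summ(post)}
    ).T

    # case rejection-point scores vs control-patient scores at matched weeks
    ctrl = df[(df["class"] == control) & (df["week"].isin(rejection_weeks))]
    ctrl = ctrl[~ctrl["patient"].isin(df[df["class"] == case]["patient"])]
    if len(rej) >= 2 and len(ctrl) >= 2:
        t_p = float(stats.ttest_ind(rej, ctrl["score"]).pvalue)
    else:
        t_p = float("nan")

    return {"by_week": by_week, "transition": transition, "rejection_vs_control_p": t_p}


def calibrate_panel(
    locked: PanelClassifier,
    matrix_new: QuantMatrix | pd.DataFrame,
    y: Mapping[str, str] | pd.Series,
) -> tuple[PanelClassifier, pd.DataFrame]:
    """Refit (w, c) of a locked panel on a migrated assay.

    Panel membership and model family are unchanged; only the weights and
    offset are re-estimated on the new platform's measurements.  Returns
    the calibrated model and a weight report comparing old and new signs.
    """
    if not locked.locked:
        raise ValueError("calibrate_panel requires a locked model")
    vals = matrix_new.values if isinstance(matrix_new, QuantMatrix) else matrix_new
    missing = [p for p in locked.panel if p not in vals.index]
    if missing:
        raise KeyError(f"panel proteins missing on new platform: {missing}")
    model = fit_lda(
        matrix_new, y, panel=locked.panel, case=locked.case, control=locked.control
    ).lock()
    report = pd.DataFrame(
        {
            "protein": locked.panel,
            "weight_old": locked.weights,
            "weight_new": model.weights,
            "sign_preserved": np.sign(locked.weights) == np.sign(model.weights),
        }
    )
    return model, report
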