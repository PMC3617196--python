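"""LDA panel classifier, cross-validation, ROC and calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from proteopanel.classifier import (
    PanelClassifier,
    calibrate_panel,
    fit_lda,
    incremental_panels,
    longitudinal_score_summary,
    roc_auc,
    score_samples,
    stratified_kfold_cv,
)
from proteopanel.design import SampleManifest
from proteopanel.matrix import QuantMatrix


def as_matrix(A, y):
    """n x p array + labels -> (QuantMatrix features x samples, label Series)."""
    samples = [f"s{i}" for i in range(A.shape[0])]
    features = [f"p{j}" for j in range(A.shape[1])]
    y = pd.Series(list(y), index=samples)
    return QuantMatrix(pd.DataFrame(A.T, index=features, columns=samples)), y


def gaussian_two_class(rng, n1, n0, mu1, mu0, sd=1.0):
    A = np.r_[
        rng.normal(mu1, sd, size=(n1, len(mu1))), rng.normal(mu0, sd, size=(n0, len(mu0)))
    ]
    return as_matrix(A, ["AR"] * n1 + ["NR"] * n0)


# ---------------------------------------------------------------------------
# fitting and scoring
# ---------------------------------------------------------------------------

def test_single_feature_equal_priors_boundary_at_midpoint():
    rng = np.random.default_rng(0)
    m, y = gaussian_two_class(rng, 20, 20, [1.0], [-1.0], sd=0.7)
    model = fit_lda(m, y, priors=(0.5, 0.5))
    assert model.weights[0] > 0
    mid = (m.values.loc["p0"][y == "AR"].mean() + m.values.loc["p0"][y == "NR"].mean()) / 2
    boundary = model.offset / model.weights[0]
    assert boundary == pytest.approx(mid, abs=1e-12)


def test_two_feature_weights_match_hand_linear_algebra():
    rng = np.random.default_rng(1)
    m, y = gaussian_two_class(rng, 10, 12, [1, 0], [0, 1])
    model = fit_lda(m, y)
    A = m.values.T.to_numpy()
    mu1, mu0 = A[:10].mean(0), A[10:].mean(0)
    d1, d0 = A[:10] - mu1, A[10:] - mu0
    S = (d1.T @ d1 + d0.T @ d0) / 22
    w = np.linalg.inv(S) @ (mu1 - mu0)
    c = w @ (mu1 + mu0) / 2 - math.log(10 / 12)
    np.testing.assert_allclose(model.weights, w, atol=1e-10)
    assert model.offset == pytest.approx(c, abs=1e-10)


def test_duplicating_samples_leaves_model_unchanged():
    rng = np.random.default_rng(2)
    m, y = gaussian_two_class(rng, 8, 9, [1, 0, 0], [0, 0.5, 1])
    model = fit_lda(m, y)
    doubled = pd.concat([m.values, m.values.add_suffix("_dup", axis=1)], axis=1)
    y2 = pd.concat([y, y.set_axis([f"{i}_dup" for i in y.index])])
    model2 = fit_lda(QuantMatrix(doubled), y2)
    np.testing.assert_allclose(model2.weights, model.weights, atol=1e-12)
    assert model2.offset == pytest.approx(model.offset, abs=1e-12)


def test_predictions_agree_with_reference_lda():
    rng = np.random.default_rng(3)
    m, y = gaussian_two_class(rng, 15, 25, [1, 0], [0, 0.8])
    model = fit_lda(m, y)
    scored = score_samples(model, m)
    ref = LinearDiscriminantAnalysis(solver="lsqr").fit(
        m.values.T.to_numpy(), (y == "AR").astype(int)
    )
    assert (scored["predicted"] == np.where(ref.predict(m.values.T.to_numpy()), "AR", "NR")).all()
    np.testing.assert_allclose(
        scored["probability"], ref.predict_proba(m.values.T.to_numpy())[:, 1], atol=1e-8
    )


def test_boundary_sample_scores_zero_probability_half():
    rng = np.random.default_rng(4)
    m, y = gaussian_two_class(rng, 10, 10, [1.0], [-1.0])
    model = fit_lda(m, y)
    x_boundary = model.offset / model.weights[0]
    probe = QuantMatrix(pd.DataFrame({"b": [x_boundary]}, index=["p0"]))
    s = score_samples(model, probe)
    assert s.loc["b", "score"] == pytest.approx(0.0, abs=1e-12)
    assert s.loc["b", "probability"] == pytest.approx(0.5, abs=1e-12)


def test_translation_equivariance_of_scores():
    rng = np.random.default_rng(5)
    m, y = gaussian_two_class(rng, 10, 12, [1, 0], [0, 1])
    shift = np.array([3.0, -2.0])
    shifted = QuantMatrix(m.values.add(pd.Series(shift, index=["p0", "p1"]), axis=0))
    s1 = score_samples(fit_lda(m, y), m)["score"]
    s2 = score_samples(fit_lda(shifted, y), shifted)["score"]
    np.testing.assert_allclose(s1, s2, atol=1e-10)


def test_probability_above_half_iff_positive_score():
    rng = np.random.default_rng(6)
    m, y = gaussian_two_class(rng, 12, 12, [0.5, 0], [0, 0.5])
    model = fit_lda(m, y)
    probe, _ = as_matrix(rng.normal(size=(1000, 2)), ["AR"] * 1000)
    s = score_samples(model, probe)
    assert ((s["probability"] > 0.5) == (s["score"] > 0)).all()


def test_singular_covariance_ridge_fallback():
    rng = np.random.default_rng(7)
    base = rng.normal(size=(12, 1))
    A = np.hstack([base, base])  # perfectly collinear features
    m, y = as_matrix(A, ["AR"] * 6 + ["NR"] * 6)
    with pytest.warns(UserWarning, match="ridge"):
        model = fit_lda(m, y)
    assert np.isfinite(model.weights).all()
    with pytest.raises(np.linalg.LinAlgError):
        fit_lda(m, y, ridge=False)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_auc_examples():
    assert roc_auc([1, 2, 3], ["NR", "NR", "AR"]) == 1.0
    assert roc_auc([5, 5, 5, 5], ["AR", "NR", "AR", "NR"]) == 0.5
    with pytest.raises(ValueError):
        roc_auc([1, 2], ["AR", "AR"])


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_pairwise_concordance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    y = np.where(rng.random(n) < 0.4, "AR", "NR")
    if len(set(y)) < 2:
        y[0] = "AR"
        y[1] = "NR"
    brute = np.mean(
        [
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in scores[y == "AR"]
            for b in scores[y == "NR"]
        ]
    )
    assert roc_auc(scores, y) == pytest.approx(brute)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(8)
    scores = rng.normal(size=40)
    y = np.where(rng.random(40) < 0.5, "AR", "NR")
    y[:2] = ["AR", "NR"]
    assert roc_auc(np.exp(scores), y) == pytest.approx(roc_auc(scores, y))
    assert roc_auc(3 * scores + 7, y) == pytest.approx(roc_auc(scores, y))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_fold_structure_exact_divisibility():
    rng = np.random.default_rng(9)
    m, y = gaussian_two_class(rng, 6, 12, [2.0], [0.0])
    report = stratified_kfold_cv(m, y, k=6, seed=0)
    folds = report.fold_assignments
    assert sorted(folds.unique()) == list(range(6))
    for f in range(6):
        members = y[folds == f]
        assert (members == "AR").sum() == 1 and (members == "NR").sum() == 2
    # partition: disjoint and exhaustive
    assert folds.notna().all() and len(folds) == 18


def test_separable_data_perfect_metrics():
    rng = np.random.default_rng(10)
    m, y = gaussian_two_class(rng, 9, 18, [5.0, 5.0], [0.0, 0.0], sd=1.0)
    report = stratified_kfold_cv(m, y, k=6, seed=1)
    assert report.sensitivity == 1.0
    assert report.specificity == 1.0
    assert report.auc == 1.0


def test_cv_matches_from_scratch_fold_loop():
    rng = np.random.default_rng(11)
    m, y = gaussian_two_class(rng, 8, 16, [0.8, 0], [0, 0.8])
    report = stratified_kfold_cv(m, y, k=4, seed=3)
    folds = report.fold_assignments
    scores = pd.Series(index=y.index, dtype=float)
    for f in sorted(folds.unique()):
        train = folds.index[folds != f]
        test = folds.index[folds == f]
        model = fit_lda(m.restrict_cols(list(train)), y.loc[train])
        scores.loc[test] = score_samples(model, m.restrict_cols(list(test)))["score"]
    np.testing.assert_allclose(report.scores["score"], scores.loc[report.scores.index])
    tp = ((scores > 0) & (y == "AR")).sum()
    fn = ((scores <= 0) & (y == "AR")).sum()
    assert report.sensitivity == pytest.approx(tp / (tp + fn))
    assert report.auc == pytest.approx(roc_auc(scores, y))


def test_incremental_panels_share_folds_and_strong_marker_first():
    rng = np.random.default_rng(12)
    n1, n0 = 12, 24
    sep = np.r_[rng.normal(5, 1, n1), rng.normal(0, 1, n0)]
    noise = rng.normal(size=n1 + n0)
    m, y = as_matrix(np.c_[sep, noise], ["AR"] * n1 + ["NR"] * n0)
    reports = incremental_panels(m, y, ["p0", "p1"], k=6, seed=0)
    assert [r.panel for r in reports] == [["p0"], ["p0", "p1"]]
    pd.testing.assert_series_equal(reports[0].fold_assignments, reports[1].fold_assignments)
    assert reports[0].auc == 1.0
    # appending a pure-noise marker barely moves the AUC
    assert abs(reports[1].auc - reports[0].auc) < 0.15


def test_weak_alone_strong_jointly_scenario():
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n1 = n0 = 30
        u = rng.normal(size=n1 + n0)
        cls = np.r_[np.ones(n1), np.zeros(n0)]
        x1 = u + rng.normal(0, 0.1, n1 + n0)
        x2 = u + 0.8 * cls + rng.normal(0, 0.3, n1 + n0)
        m, y = as_matrix(np.c_[x1, x2], ["AR"] * n1 + ["NR"] * n0)
        reports = incremental_panels(m, y, ["p1", "p0"], k=6, seed=seed)
        if reports[-1].auc > reports[0].auc:
            wins += 1
    assert wins >= 8


# ---------------------------------------------------------------------------
# longitudinal summaries
# ---------------------------------------------------------------------------

def make_longitudinal():
    rows = []
    scores = {}
    # AR patient: NR at weeks 1-2, AR at 3-4, NR at 5; planted bump +2
    for pid, pattern in [("pa", ["NR", "NR", "AR", "AR", "NR"]), ("pn", ["NR"] * 5)]:
        for w, cls in enumerate(pattern, start=1):
            sid = f"{pid}_w{w}"
            rows.append((sid, pid, cls, w, 50, "M"))
            scores[sid] = 2.0 if cls == "AR" else 0.0
    manifest = SampleManifest(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "class", "week", "age", "sex"])
    )
    vals = pd.DataFrame({sid: [v] for sid, v in scores.items()}, index=["p0"])
    return manifest, QuantMatrix(vals)


def test_transition_table_recovers_planted_trajectory():
    manifest, m = make_longitudinal()
    model = PanelClassifier(panel=["p0"], weights=np.array([1.0]), offset=0.0, priors=(0.5, 0.5))
    out = longitudinal_score_summary(model, m, manifest)
    tr = out["transition"]
    assert tr.loc["pre_rejection", "mean"] == pytest.approx(0.0)
    assert tr.loc["rejection", "mean"] == pytest.approx(2.0)
    assert tr.loc["post_rejection", "mean"] == pytest.approx(0.0)
    by_week = out["by_week"]
    single = by_week[(by_week["class"] == "AR") & (by_week["week"] == 3)]
    assert np.isnan(single["se"].iloc[0])  # single sample: SE reported absent


def test_zero_weights_give_flat_scores():
    manifest, m = make_longitudinal()
    model = PanelClassifier(panel=["p0"], weights=np.array([0.0]), offset=0.0, priors=(0.5, 0.5))
    out = longitudinal_score_summary(model, m, manifest)
    assert (out["by_week"]["mean"] == 0).all()


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_fixed_point_and_lock_required():
    rng = np.random.default_rng(13)
    m, y = gaussian_two_class(rng, 10, 14, [1, 0], [0, 1])
    model = fit_lda(m, y)
    with pytest.raises(ValueError, match="locked"):
        calibrate_panel(model, m, y)
    locked = model.lock()
    recal, report = calibrate_panel(locked, m, y)
    np.testing.assert_allclose(recal.weights, locked.weights, atol=1e-10)
    assert recal.offset == pytest.approx(locked.offset, abs=1e-10)
    assert report["sign_preserved"].all()


def test_calibration_restores_labels_after_affine_platform_shift():
    rng = np.random.default_rng(14)
    m, y = gaussian_two_class(rng, 12, 16, [1, 0], [0, 1])
    locked = fit_lda(m, y).lock()
    scale = pd.Series([2.5, 0.4], index=["p0", "p1"])
    shift = pd.Series([10.0, -3.0], index=["p0", "p1"])
    new = QuantMatrix(m.values.mul(scale, axis=0).add(shift, axis=0))
    recal, _ = calibrate_panel(locked, new, y)
    old_pred = score_samples(locked, m)["predicted"]
    new_pred = score_samples(recal, new)["predicted"]
    assert (old_pred == new_pred).all()


def test_calibration_missing_panel_member_lists_it():
    rng = np.random.default_rng(15)
    m, y = gaussian_two_class(rng, 8, 8, [1, 0], [0, 1])
    locked = fit_lda(m, y).lock()
    partial = QuantMatrix(m.values.loc[["p0"]])
    with pytest.raises(KeyError, match="p1"):
        calibrate_panel(locked, partial, y)


def test_weight_signs_stable_under_moderate_noise():
    rng = np.random.default_rng(16)
    m, y = gaussian_two_class(rng, 30, 30, [1.0, -1.0], [0.0, 0.0], sd=0.5)
    locked = fit_lda(m, y).lock()
    agree = 0
    for seed in range(10):
        r2 = np.random.default_rng(1000 + seed)
        noisy = QuantMatrix(m.values + r2.normal(0, 0.1, m.values.shape))
        recal, report = calibrate_panel(locked, noisy, y)
        agree += report["sign_preserved"].all()
    assert agree >= 9


def test_model_json_roundtrip(tmp_path):
    model = PanelClassifier(
        panel=["a", "b"], weights=np.array([1.5, -2.0]), offset=0.3, priors=(0.4, 0.6)
    ).lock()
    path = tmp_path / "model.json"
    model.to_json(path)
    back = PanelClassifier.from_json(path)
    assert back.panel == model.panel
    np.testing.assert_allclose(back.weights, model.weights)
    assert back.locked
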