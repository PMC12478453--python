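"""Cohort statistics: t-test, volcano, Pearson, ROC, embeddings, SVM-LOOCV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special
from scipy.optimize import minimize
from sklearn.metrics import silhouette_score

from seraman import stats
from seraman.exceptions import AxisError, DegenerateDataError, ParameterError
from seraman.io import PointSpectrum


# ---------------------------------------------------------------------------
# t-test


def test_ttest_identical_groups():
    x = [1.0, 2.0, 3.0]
    t, p = stats.ttest_homoscedastic(x, x)
    assert t == 0.0 and p == 1.0


def test_ttest_large_shift_significant():
    x = np.array([1.0, 2.0, 3.0])
    _, p = stats.ttest_homoscedastic(x, x + 40.0)
    assert p < 1e-4


def test_ttest_zero_pooled_variance():
    with pytest.raises(DegenerateDataError):
        stats.ttest_homoscedastic([1.0, 1.0], [1.0, 1.0])


def _p_by_quadrature(t_stat, df):
    """Two-sided p by numerical integration of the t density."""
    c = special.gamma((df + 1) / 2) / (
        np.sqrt(df * np.pi) * special.gamma(df / 2)
    )
    dens = lambda u: c * (1 + u**2 / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(dens, abs(t_stat), np.inf)
    return 2 * tail


def test_ttest_p_matches_quadrature():
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.normal(0, 1, rng.integers(3, 12))
        y = rng.normal(0.5, 1.3, rng.integers(3, 12))
        t, p = stats.ttest_homoscedastic(x, y)
        assert abs(p - _p_by_quadrature(t, x.size + y.size - 2)) < 1e-10


def test_ttest_null_calibration():
    """Type-I error at alpha = 0.05 under a normal null, n = 10/10."""
    rng = np.random.default_rng(12345)
    reps = 10_000
    x = rng.normal(size=(reps, 10))
    y = rng.normal(size=(reps, 10))
    rejections = sum(
        stats.ttest_homoscedastic(x[i], y[i])[1] < 0.05 for i in range(reps)
    )
    assert 0.04 <= rejections / reps <= 0.06


# ---------------------------------------------------------------------------
# volcano


def _table(rng, n=12, p=6):
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(
        rng.lognormal(0, 0.2, (n, p)),
        index=ids,
        columns=[f"f{j}" for j in range(p)],
    )


def test_volcano_case_reference_symmetry():
    rng = np.random.default_rng(1)
    X = _table(rng)
    groups = pd.Series(["a"] * 6 + ["b"] * 6, index=X.index)
    v1 = stats.volcano(X, groups, "a", "b")
    v2 = stats.volcano(X, groups, "b", "a")
    np.testing.assert_allclose(v1["fold_change"], 1 / v2["fold_change"])
    np.testing.assert_allclose(v1["p_value"], v2["p_value"])


def test_volcano_same_group_fold_change_one():
    rng = np.random.default_rng(2)
    X = _table(rng)
    groups = pd.Series(["a"] * 6 + ["b"] * 6, index=X.index)
    sub = X.loc[groups == "a"]
    half = pd.Series(["c1"] * 3 + ["c2"] * 3, index=sub.index)
    v = stats.volcano(sub, half, "c1", "c2")
    # no true effect: fold changes scatter around 1
    assert np.all(np.abs(np.log2(v["fold_change"])) < 1.0)


def test_volcano_detects_injected_shift():
    rng = np.random.default_rng(3)
    n = 20
    X = pd.DataFrame(
        rng.lognormal(0, 0.15, (2 * n, 5)),
        index=[f"s{i}" for i in range(2 * n)],
        columns=list("abcde"),
    )
    X.loc[X.index[:n], "c"] *= 2.0
    groups = pd.Series(["case"] * n + ["ref"] * n, index=X.index)
    v = stats.volcano(X, groups, "case", "ref").set_index("feature")
    assert v.loc["c", "significant"]
    assert abs(v.loc["c", "fold_change"] - 2) / 2 < 0.2


def test_volcano_missing_group_errors():
    rng = np.random.default_rng(4)
    X = _table(rng)
    groups = pd.Series(["a"] * 12, index=X.index)
    with pytest.raises(ParameterError):
        stats.volcano(X, groups, "a", "nope")


def test_volcano_bh_flag_adds_q_values():
    rng = np.random.default_rng(5)
    X = _table(rng, n=16, p=10)
    groups = pd.Series(["a"] * 8 + ["b"] * 8, index=X.index)
    v = stats.volcano(X, groups, "a", "b", bh=True)
    assert "q_value" in v.columns
    assert (v["q_value"].dropna() >= v["p_value"].dropna() - 1e-12).all()


# ---------------------------------------------------------------------------
# Pearson


def test_pearson_self_is_identity_diagonal():
    rng = np.random.default_rng(6)
    X = _table(rng)
    r = stats.pearson_matrix(X)
    np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)
    np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12)


def test_pearson_anticorrelation():
    x = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    y = pd.DataFrame({"y": [-1.0, -2.0, -3.0, -4.0]}, index=list("abcd"))
    assert stats.pearson_matrix(x, y).iloc[0, 0] == pytest.approx(-1.0)


def test_pearson_matches_bruteforce_formula():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(10, 4)), index=range(10))
    Y = pd.DataFrame(rng.normal(size=(10, 3)), index=range(10))
    r = stats.pearson_matrix(X, Y).to_numpy()
    for i in range(4):
        for j in range(3):
            xi, yj = X.iloc[:, i], Y.iloc[:, j]
            brute = (
                ((xi - xi.mean()) * (yj - yj.mean())).sum()
                / np.sqrt(((xi - xi.mean()) ** 2).sum())
                / np.sqrt(((yj - yj.mean()) ** 2).sum())
            )
            assert abs(r[i, j] - brute) < 1e-12


def test_pearson_zero_variance_marked_nan():
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
    r = stats.pearson_matrix(X)
    assert np.isnan(r.loc["const", "x"])


def test_pearson_needs_three_samples():
    X = pd.DataFrame({"x": [1.0, 2.0]})
    with pytest.raises(DegenerateDataError):
        stats.pearson_matrix(X)


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    r = stats.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=50,
                      seed=0)
    assert r.auc == 1.0
    assert r.ci_low <= r.auc <= r.ci_high


def test_roc_all_ties():
    r = stats.roc_auc(np.ones(10), [0, 1] * 5, n_boot=50, seed=0)
    assert r.auc == 0.5


def test_roc_no_autoflip():
    r = stats.roc_auc([3, 2, 1], [1, 0, 0], n_boot=50, seed=0)
    assert r.auc == 1.0
    r = stats.roc_auc([1, 2, 3], [1, 0, 0], n_boot=50, seed=0)
    assert r.auc == 0.0


def test_roc_single_class_errors():
    with pytest.raises(DegenerateDataError):
        stats.roc_auc([1.0, 2.0], [1, 1], n_boot=10)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 25), st.integers(2, 25))
def test_roc_equals_pair_counting(seed, n_pos, n_neg):
    """Rank-formula AUC equals exhaustive pair enumeration, ties as 1/2."""
    rng = np.random.default_rng(seed)
    # discrete scores force ties
    scores = rng.integers(0, 6, n_pos + n_neg).astype(float)
    labels = np.r_[np.ones(n_pos), np.zeros(n_neg)]
    r = stats.roc_auc(scores, labels, n_boot=2, seed=0)
    pos, neg = scores[:n_pos], scores[n_pos:]
    brute = np.mean(
        [0.5 if p == q else float(p > q) for p in pos for q in neg]
    )
    assert r.auc == pytest.approx(brute, abs=1e-12)


def test_roc_gaussian_shift_matches_theory():
    """AUC for N(2,1) vs N(0,1) concentrates near Phi(sqrt(2)) = 0.921."""
    rng = np.random.default_rng(99)
    scores = np.r_[rng.normal(2, 1, 200), rng.normal(0, 1, 200)]
    labels = np.r_[np.ones(200), np.zeros(200)]
    r = stats.roc_auc(scores, labels, n_boot=100, seed=1)
    assert abs(r.auc - 0.921) < 0.03


# ---------------------------------------------------------------------------
# embeddings


def test_pca_line_explains_everything():
    t = np.linspace(0, 1, 10)
    X = pd.DataFrame({"a": t, "b": 2 * t, "c": -t}, index=range(10))
    emb = stats.pca(X, k=2, scale=False)
    assert emb.explained_variance[0] == pytest.approx(1.0)


def test_pca_matches_eigendecomposition():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(15, 5)), index=range(15))
    emb = stats.pca(X, k=3, scale=True)
    Z = (X - X.mean()) / X.std(ddof=1)
    C = np.cov(Z.to_numpy().T, ddof=1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    expected = Z.to_numpy() @ V[:, order[:3]]
    got = emb.coordinates.to_numpy()
    for j in range(3):
        sign = np.sign(np.dot(expected[:, j], got[:, j]))
        np.testing.assert_allclose(got[:, j], sign * expected[:, j], atol=1e-8)


def test_pca_variance_conservation():
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(12, 4)), index=range(12))
    emb = stats.pca(X, k=4, scale=True)
    Z = (X - X.mean()) / X.std(ddof=1)
    total = np.var(Z.to_numpy(), axis=0, ddof=1).sum()
    scores_var = np.var(emb.coordinates.to_numpy(), axis=0, ddof=1).sum()
    assert scores_var == pytest.approx(total, rel=1e-10)


def test_pca_rank_error():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 2)))
    with pytest.raises(ParameterError):
        stats.pca(X, k=3)


def test_tsne_deterministic_and_separates_clusters():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(
        np.r_[rng.normal(0, 1, (30, 6)), rng.normal(10, 1, (30, 6))],
        index=[f"s{i}" for i in range(60)],
    )
    labels = np.r_[np.zeros(30), np.ones(30)]
    e1 = stats.pca_tsne(X, seed=3)
    e2 = stats.pca_tsne(X, seed=3)
    np.testing.assert_array_equal(e1.coordinates.to_numpy(),
                                  e2.coordinates.to_numpy())
    assert silhouette_score(e1.coordinates.to_numpy(), labels) > 0.5


def test_tsne_single_cluster_no_structure():
    rng = np.random.default_rng(11)
    X = pd.DataFrame(rng.normal(0, 1, (24, 5)), index=range(24))
    labels = np.r_[np.zeros(12), np.ones(12)]
    scores = [
        silhouette_score(
            stats.pca_tsne(X, seed=s).coordinates.to_numpy(), labels
        )
        for s in range(4)
    ]
    assert np.mean(scores) < 0.25


def test_tsne_needs_eight_samples():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
    with pytest.raises(ParameterError):
        stats.pca_tsne(X)


# ---------------------------------------------------------------------------
# PCA + SVM LOOCV


def _separable(rng, n=20, gap=8.0):
    X = pd.DataFrame(
        np.r_[rng.normal(0, 1, (n // 2, 4)),
              rng.normal(gap, 1, (n - n // 2, 4))],
        index=[f"s{i}" for i in range(n)],
    )
    y = pd.Series(["a"] * (n // 2) + ["b"] * (n - n // 2), index=X.index)
    return X, y


def test_svm_separable_perfect_accuracy():
    X, y = _separable(np.random.default_rng(13))
    report = stats.pca_svm_loocv(X, y, c_grid=[1, 10, 100])
    assert report.loocv_accuracy == 1.0
    assert 1 <= report.chosen_C <= 100
    assert len(report.fold_C) == len(X)


def test_svm_order_invariance():
    X, y = _separable(np.random.default_rng(14), n=12, gap=3.0)
    r1 = stats.pca_svm_loocv(X, y, c_grid=[1, 10])
    perm = np.random.default_rng(0).permutation(len(X))
    r2 = stats.pca_svm_loocv(X.iloc[perm], y.iloc[perm], c_grid=[1, 10])
    assert r1.loocv_accuracy == r2.loocv_accuracy


def test_svm_class_size_guard():
    X, _ = _separable(np.random.default_rng(15), n=8)
    y = pd.Series(["a"] * 6 + ["b"] * 2, index=X.index)
    with pytest.raises(DegenerateDataError):
        stats.pca_svm_loocv(X, y, c_grid=[1])


def _svm_dual_oracle(X, y, C):
    """Soft-margin linear SVM via the dual QP (SLSQP), for tiny n."""
    n = len(y)
    K = X @ X.T
    Q = K * np.outer(y, y)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    res = minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = (a * y) @ X
    sv = (a > 1e-6) & (a < C - 1e-6)
    if sv.any():
        b = np.mean(y[sv] - X[sv] @ w)
    else:
        margins = y - X @ w
        b = (margins.min() + margins.max()) / 2
    return w, b


def test_svm_loocv_matches_qp_oracle():
    """Held-out predictions of the nested procedure equal a brute-force
    dual-QP linear SVM refit on each fold's 2D PCA scores."""
    rng = np.random.default_rng(16)
    X = pd.DataFrame(
        np.r_[rng.normal(0, 1, (3, 2)), rng.normal(4, 1, (3, 2))],
        index=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=X.index)
    c_grid = [1, 10]
    report = stats.pca_svm_loocv(X, labels, c_grid=c_grid)

    Xv = X.to_numpy()
    yv = np.where(labels.to_numpy() == "a", -1.0, 1.0)
    n = len(yv)

    def fold_coords(train):
        mu = Xv[train].mean(axis=0)
        sd = Xv[train].std(axis=0, ddof=1)
        Z = (Xv - mu) / sd
        _, _, Vt = np.linalg.svd(Z[train] - Z[train].mean(axis=0),
                                 full_matrices=False)
        return (Z - Z[train].mean(axis=0)) @ Vt[:2].T

    def loocv_acc(coords, yy, C):
        correct = 0
        for i in range(len(yy)):
            tr = np.setdiff1d(np.arange(len(yy)), [i])
            w, b = _svm_dual_oracle(coords[tr], yy[tr], C)
            correct += int(np.sign(coords[i] @ w + b) == yy[i])
        return correct / len(yy)

    for i in range(n):
        train = np.setdiff1d(np.arange(n), [i])
        coords = fold_coords(train)
        accs = [loocv_acc(coords[train], yv[train], C) for C in c_grid]
        best_C = c_grid[int(np.argmax(accs))]
        w, b = _svm_dual_oracle(coords[train], yv[train], best_C)
        pred = "a" if np.sign(coords[i] @ w + b) < 0 else "b"
        assert report.predictions.iloc[i] == pred, i


# ---------------------------------------------------------------------------
# NAR stratification


@pytest.mark.parametrize(
    "score,expected",
    [(0.0, "complete"), (7.9, "complete"), (8.0, "partial"),
     (14.0, "partial"), (14.1, "poor"), (20.0, "poor")],
)
def test_stratify_nar_boundaries(score, expected):
    assert stats.stratify_nar(score) == expected


def test_stratify_nar_rejects_negative():
    with pytest.raises(ParameterError):
        stats.stratify_nar(-1.0)


def test_stratify_series_keeps_nan():
    s = pd.Series([5.0, np.nan, 16.0])
    out = stats.stratify_nar_series(s)
    assert out[0] == "complete" and out[2] == "poor"
    assert pd.isna(out[1])


# ---------------------------------------------------------------------------
# difference spectra


def test_difference_spectrum_basics(axis):
    a = PointSpectrum("a", 0, axis, np.sin(axis / 100))
    b = PointSpectrum("b", 0, axis, np.cos(axis / 100))
    d_ab = stats.difference_spectrum(a, b)
    d_ba = stats.difference_spectrum(b, a)
    np.testing.assert_allclose(d_ab.intensities, -d_ba.intensities)
    zero = stats.difference_spectrum(a, a)
    assert not zero.intensities.any()


def test_difference_spectrum_grid_mismatch(axis):
    a = PointSpectrum("a", 0, axis, np.ones(axis.size))
    b = PointSpectrum("b", 0, axis[:-100] + 0.5, np.ones(axis.size - 100))
    with pytest.raises(AxisError):
        stats.difference_spectrum(a, b)


def test_difference_localizes_injected_band(axis):
    bump = 0.8 * np.exp(-4 * np.log(2) * ((axis - 852.0) / 8.0) ** 2)
    base = np.sin(axis / 400)
    a = PointSpectrum("a", 0, axis, base + bump)
    b = PointSpectrum("b", 0, axis, base)
    d = stats.difference_spectrum(a, b)
    assert abs(axis[np.argmax(np.abs(d.intensities))] - 852.0) <= 5
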