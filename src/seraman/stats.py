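"""Cross-sample cohort statistics.

Volcano analysis (ratio-of-means fold change, pooled-variance t-test,
raw p < 0.05 significance with optional Benjamini-Hochberg behind a
flag), Pearson correlation matrices, univariate ROC-AUC with stratified
bootstrap CIs, PCA and PCA-tSNE embeddings, nested leave-one-out
PCA+linear-SVM classification, neoadjuvant-rectal-score responder
stratification, and group-mean difference spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from seraman.exceptions import AxisError, DegenerateDataError, ParameterError
from seraman.io import PointSpectrum
from seraman.peaks import PeakTable

# ---------------------------------------------------------------------------
# results containers


@dataclass
class RocResult:
    """Mann-Whitney AUC with a stratified bootstrap percentile CI."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class Embedding:
    """A 2D (or k-D) sample embedding."""

    method: str  # "pca" | "pca_tsne"
    coordinates: pd.DataFrame  # samples x components
    explained_variance: np.ndarray | None = None  # pca only
    seed: int | None = None


@dataclass
class CvReport:
    """Leave-one-out cross-validation report for one feature set."""

    feature_set: str
    loocv_accuracy: float
    chosen_C: int  # modal choice across outer folds
    fold_C: list[int] = field(default_factory=list)
    predictions: pd.Series | None = None  # held-out prediction per sample


# ---------------------------------------------------------------------------
# univariate tests


def ttest_homoscedastic(x, y) -> tuple[float, float]:
    """Unpaired two-sided Student's t-test with pooled variance.

    Returns ``(t_statistic, p_value)`` with ``df = n_x + n_y - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    sp2 = (
        (x.size - 1) * np.var(x, ddof=1) + (y.size - 1) * np.var(y, ddof=1)
    ) / (x.size + y.size - 2)
    if sp2 == 0.0:
        raise DegenerateDataError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def volcano(
    table: PeakTable | pd.DataFrame,
    groups: pd.Series,
    case: str,
    reference: str,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-feature fold change (case mean / reference mean) and t-test p.

    ``significant`` flags raw p < alpha; with ``bh=True`` the flag is on
    Benjamini-Hochberg adjusted q-values instead (the adjusted values are
    then reported in a ``q_value`` column).
    """
    frame = table.frame if isinstance(table, PeakTable) else table
    groups = groups.reindex(frame.index)
    for label in (case, reference):
        if (groups == label).sum() < 2:
            raise ParameterError(f"group {label!r} absent or has < 2 samples")
    X_case = frame.loc[groups == case]
    X_ref = frame.loc[groups == reference]
    rows = []
    for col in frame.columns:
        mc, mr = X_case[col].mean(), X_ref[col].mean()
        fc = mc / mr
        try:
            _, p = ttest_homoscedastic(X_case[col], X_ref[col])
        except DegenerateDataError:
            # constant feature (e.g. the ratiometric denominator column)
            p = np.nan
        rows.append((col, fc, np.log2(fc) if fc > 0 else np.nan, p))
    out = pd.DataFrame(rows, columns=["feature", "fold_change", "log2_fc", "p_value"])
    if bh:
        p = out["p_value"].to_numpy()
        finite = np.isfinite(p)
        m = int(finite.sum())
        q = np.full(p.size, np.nan)
        order = np.argsort(p[finite])
        prev = 1.0
        idx_finite = np.flatnonzero(finite)
        for rank, j in enumerate(order[::-1]):
            prev = min(prev, p[idx_finite[j]] * m / (m - rank))
            q[idx_finite[j]] = prev
        out["q_value"] = q
        out["significant"] = out["q_value"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


# ---------------------------------------------------------------------------
# correlations


def pearson_matrix(
    X: pd.DataFrame, Y: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pairwise Pearson r between the columns of X and Y (rows = samples).

    Computed over the samples shared by both frames.  Zero-variance
    features yield NaN in their rows/columns.
    """
    if Y is None:
        Y = X
    common = X.index.intersection(Y.index)
    if len(common) < 3:
        raise DegenerateDataError(
            f"need >= 3 shared samples for correlation, have {len(common)}"
        )
    Xv = X.loc[common].to_numpy(dtype=float)
    Yv = Y.loc[common].to_numpy(dtype=float)
    n = len(common)

    def _standardize(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (M - mu) / sd
        Z[:, sd == 0] = np.nan
        return Z

    Zx, Zy = _standardize(Xv), _standardize(Yv)
    r = Zx.T @ Zy / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=X.columns, columns=Y.columns)


# ---------------------------------------------------------------------------
# ROC


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Univariate ROC AUC with a 95% stratified bootstrap percentile CI.

    AUC is the Mann-Whitney pair-counting statistic (ties credited 1/2),
    computed from midranks.  Orientation is fixed: the positive class is
    hypothesised to score higher, and the AUC is reported as computed —
    no auto-flipping below 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("both classes must be present for ROC")
    auc = _auc_from_ranks(pos, neg)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[b] = _auc_from_ranks(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(auc, float(lo), float(hi), int(pos.size), int(neg.size))


def _auc_from_ranks(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# embeddings


def _scaled(X: pd.DataFrame, scale: bool) -> np.ndarray:
    V = X.to_numpy(dtype=float)
    V = V - V.mean(axis=0)
    if scale:
        sd = V.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        V = V / sd
    return V


def pca(X: pd.DataFrame, k: int = 2, scale: bool = True) -> Embedding:
    """PCA scores on the first k axes, with explained-variance fractions.

    Features are column-centred and, by default, auto-scaled to unit
    variance (peak and protein features live on incommensurate scales).
    """
    n, p = X.shape
    if k > min(n - 1, p):
        raise ParameterError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    V = _scaled(X, scale)
    model = PCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(V)
    return Embedding(
        method="pca",
        coordinates=pd.DataFrame(
            coords, index=X.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_variance=model.explained_variance_ratio_,
    )


def pca_tsne(
    X: pd.DataFrame,
    n_pcs: int = 10,
    perplexity: float = 30.0,
    seed: int = 0,
    scale: bool = True,
) -> Embedding:
    """PCA to ``n_pcs`` dimensions, then tSNE to 2D.

    Perplexity is capped at (n-1)/3 so small cohorts remain feasible.
    Deterministic for a fixed seed.
    """
    n = X.shape[0]
    if n < 8:
        raise ParameterError(f"tSNE needs n >= 8 samples, have {n}")
    perplexity = min(perplexity, (n - 1) / 3)
    if perplexity < 1:
        raise ParameterError("perplexity collapsed below 1")
    n_pcs = min(n_pcs, n - 1, X.shape[1])
    V = _scaled(X, scale)
    scores = PCA(n_components=n_pcs, svd_solver="full").fit_transform(V)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
    ).fit_transform(scores)
    return Embedding(
        method="pca_tsne",
        coordinates=pd.DataFrame(
            coords, index=X.index, columns=["TSNE1", "TSNE2"]
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PCA + linear SVM, leave-one-out


def _loocv_accuracy(scores: np.ndarray, y: np.ndarray, C: float) -> float:
    """Plain LOOCV accuracy of a linear SVM on precomputed coordinates."""
    n = scores.shape[0]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = SVC(kernel="linear", C=C)
        clf.fit(scores[mask], y[mask])
        correct += int(clf.predict(scores[i : i + 1])[0] == y[i])
    return correct / n


def pca_svm_loocv(
    X: pd.DataFrame,
    labels: pd.Series,
    c_grid=range(1, 101),
    n_components: int = 2,
    scale: bool = True,
    nested: bool = True,
    feature_set: str = "features",
) -> CvReport:
    """Leave-one-out evaluation of a PCA(2) + linear-SVM classifier.

    For each held-out sample the scaler, PCA and SVM are fit on the
    remaining n-1 samples only.  The SVM cost C is chosen from ``c_grid``
    by an inner LOOCV on the training fold (ties break to the smallest
    C), so hyperparameter selection never sees the held-out sample.  Set
    ``nested=False`` for the leaky variant (single global PCA and C
    choice) for comparison.
    """
    y = labels.reindex(X.index).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise DegenerateDataError(
            "binary labels with >= 3 samples per class required"
        )
    if X.shape[0] < 6:
        raise DegenerateDataError("need n >= 6 samples for LOOCV")
    c_grid = sorted(int(c) for c in c_grid)
    n = X.shape[0]
    Xv = X.to_numpy(dtype=float)

    def _fit_coords(train_idx):
        mu = Xv[train_idx].mean(axis=0)
        sd = Xv[train_idx].std(axis=0, ddof=1) if scale else np.ones(Xv.shape[1])
        sd = np.where(sd == 0, 1.0, sd)
        Z = (Xv - mu) / sd
        k = min(n_components, len(train_idx) - 1, Xv.shape[1])
        model = PCA(n_components=k, svd_solver="full").fit(Z[train_idx])
        return model.transform(Z)

    preds = np.empty(n, dtype=object)
    fold_C: list[int] = []
    if nested:
        for i in range(n):
            train = np.setdiff1d(np.arange(n), [i])
            coords = _fit_coords(train)
            inner_acc = [
                _loocv_accuracy(coords[train], y[train], C) for C in c_grid
            ]
            best_C = c_grid[int(np.argmax(inner_acc))]
            clf = SVC(kernel="linear", C=best_C)
            clf.fit(coords[train], y[train])
            preds[i] = clf.predict(coords[i : i + 1])[0]
            fold_C.append(best_C)
    else:
        coords = _fit_coords(np.arange(n))
        accs = [_loocv_accuracy(coords, y, C) for C in c_grid]
        best_C = c_grid[int(np.argmax(accs))]
        fold_C = [best_C] * n
        for i in range(n):
            train = np.setdiff1d(np.arange(n), [i])
            clf = SVC(kernel="linear", C=best_C)
            clf.fit(coords[train], y[train])
            preds[i] = clf.predict(coords[i : i + 1])[0]
    accuracy = float(np.mean(preds == y))
    modal_C = int(pd.Series(fold_C).mode().min())
    return CvReport(
        feature_set=feature_set,
        loocv_accuracy=accuracy,
        chosen_C=modal_C,
        fold_C=fold_C,
        predictions=pd.Series(preds, index=X.index, name="prediction"),
    )


# ---------------------------------------------------------------------------
# responder stratification


RESPONDER_CLASSES = ("complete", "partial", "poor")


def stratify_nar(nar_score: float) -> str:
    """Neoadjuvant rectal score -> responder class.

    complete: NAR < 8; partial: 8 <= NAR <= 14 (boundaries inclusive);
    poor: NAR > 14.  Lower scores indicate better response.
    """
    if nar_score < 0 or not np.isfinite(nar_score):
        raise ParameterError(f"NAR score must be finite and >= 0, got {nar_score}")
    if nar_score < 8:
        return "complete"
    if nar_score <= 14:
        return "partial"
    return "poor"


def stratify_nar_series(nar_scores: pd.Series) -> pd.Series:
    """Vectorised :func:`stratify_nar`; NaN scores stay NaN."""
    return nar_scores.map(
        lambda s: np.nan if pd.isna(s) else stratify_nar(float(s))
    )


# ---------------------------------------------------------------------------
# difference spectra


def difference_spectrum(mean_a, mean_b) -> PointSpectrum:
    """Channel-wise difference a - b of two mean spectra on one grid."""
    if not np.array_equal(mean_a.wavenumbers, mean_b.wavenumbers):
        raise AxisError("difference spectrum requires identical grids")
    return PointSpectrum(
        sample_id=f"{mean_a.sample_id}-{mean_b.sample_id}",
        point_index=0,
        wavenumbers=mean_a.wavenumbers.copy(),
        intensities=mean_a.intensities - mean_b.intensities,
    )
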