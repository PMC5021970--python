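"""Group-level statistics: permutation tests, correlations, ROC, PCA.

The primary two-group test is a label-permutation test on the absolute mean
difference: group labels are shuffled (preserving group sizes) and the
statistic recomputed, by default 100,000 times; the p-value uses the add-one
estimator ``(1 + #{perm >= observed}) / (n_perm + 1)`` and is therefore never
exactly zero. The statistic is an absolute difference, so the test is
two-sided by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

__all__ = [
    "PermutationResult",
    "ROCResult",
    "permutation_test",
    "spearman",
    "roc_auc",
    "pca_embed",
    "correlation_clustermap",
    "group_feature_tests",
]


@dataclass
class PermutationResult:
    observed: float
    n_perm: int
    p_value: float
    seed: int | None = None


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100_000,
    seed: int | None = None,
    batch: int = 20_000,
) -> PermutationResult:
    """Two-group permutation test on the absolute mean difference.

    Labels are reshuffled uniformly among the pooled observations keeping the
    original group sizes; ``p = (1 + #{|Δ_perm| >= |Δ_obs|}) / (n_perm + 1)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    observed = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    nx, n = len(x), len(pooled)
    # permuted means of the same values differ from the observed one by a few
    # ulp depending on summation order; count such exact ties as exceedances
    tol = 1e-9 * (abs(observed) + float(np.abs(pooled).max()) + 1.0)
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = rng.permuted(np.broadcast_to(pooled, (b, n)), axis=1)
        stat = np.abs(perm[:, :nx].mean(axis=1) - perm[:, nx:].mean(axis=1))
        exceed += int((stat >= observed - tol).sum())
        done += b
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(float(observed), n_perm, float(p), seed)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    p_value: float | None = None


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    positive_label=1,
    n_perm: int | None = None,
    seed: int | None = None,
) -> ROCResult:
    """ROC curve and trapezoidal AUC (higher score = predicted positive).

    The AUC equals the fraction of (positive, negative) pairs ordered
    correctly, ties counted one half. With ``n_perm`` set, a permutation
    p-value against AUC = 0.5 is computed by reshuffling labels; otherwise
    the Mann-Whitney normal approximation is used when a p-value is needed.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, float)
    y = np.asarray(labels) == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    p_value = None
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            f, t, _ = roc_curve(yp.astype(int), scores)
            if abs(np.trapezoid(t, f) - 0.5) >= abs(auc - 0.5):
                count += 1
        p_value = (1 + count) / (n_perm + 1)
    return ROCResult(thr, tpr, fpr, auc, p_value)


def mannwhitney_auc_pvalue(scores: np.ndarray, labels: np.ndarray, positive_label=1) -> float:
    """Fast normal-approximation p-value for AUC vs 0.5 (two-sided)."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels) == positive_label
    res = sps.mannwhitneyu(scores[y], scores[~y], alternative="two-sided")
    return float(res.pvalue)


def pca_embed(
    table: pd.DataFrame | np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of z-scored features -> (scores, loadings, variance fractions).

    Constant features are dropped with a warning (their z-score is undefined).
    """
    X = np.asarray(table, float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    if np.isnan(X).any():
        raise ValueError("missing values: impute or drop before PCA")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) before PCA")
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    return scores, pca.components_, pca.explained_variance_ratio_


@dataclass
class ClustermapResult:
    correlations: pd.DataFrame  # reordered Spearman rho matrix
    order: list[str]
    linkage: np.ndarray = field(repr=False, default=None)


def correlation_clustermap(table: pd.DataFrame) -> ClustermapResult:
    """Pairwise-complete Spearman correlations, hierarchically reordered.

    Rows/columns are reordered by average-linkage agglomerative clustering on
    Euclidean distances between the rows of the correlation matrix, the
    standard layout for feature-by-feature correlation heatmaps.
    """
    numeric = table.select_dtypes("number")
    if numeric.shape[1] < 3:
        raise ValueError("need at least 3 numeric variables")
    for col in numeric.columns:
        if numeric[col].dropna().nunique() < 2:
            raise ValueError(f"variable {col!r} has zero variance")
    rho = numeric.corr(method="spearman")  # pairwise-complete by construction
    Z = hierarchy.linkage(rho.to_numpy(), method="average", metric="euclidean")
    order_idx = hierarchy.leaves_list(Z)
    order = [rho.columns[i] for i in order_idx]
    return ClustermapResult(rho.loc[order, order], order, Z)


def group_feature_tests(
    table: pd.DataFrame,
    features: list[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("patient", "control"),
    n_perm: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation-test every feature between two groups; one row per feature."""
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(features)) % (2**31)
    for feat, s in zip(features, child_seeds):
        xa = a[feat].dropna().to_numpy()
        xb = b[feat].dropna().to_numpy()
        res = permutation_test(xa, xb, n_perm=n_perm, seed=int(s))
        rows.append(
            {
                "feature": feat,
                "mean_" + groups[0]: xa.mean(),
                "mean_" + groups[1]: xb.mean(),
                "abs_mean_diff": res.observed,
                "p_value": res.p_value,
                "n_" + groups[0]: len(xa),
                "n_" + groups[1]: len(xb),
            }
        )
    return pd.DataFrame(rows)
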