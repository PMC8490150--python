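"""Subpopulation clustering and per-cluster marker statistics.

Organelle spectra (rows of the selected-feature matrix, RMS-normalized) are
partitioned by k-means; the number of clusters is chosen from the
within-cluster sum of squares (WCSS) curve by the maximum-second-difference
elbow rule.  Marker features are found per cluster by a one-vs-rest
two-sided Wilcoxon rank-sum test with Benjamini–Hochberg correction across
features within each cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .spectra import PeakMatrix

__all__ = [
    "ClusterResult",
    "rms_normalize",
    "kmeans_partition",
    "marker_tests",
    "wilcoxon_rank_sum",
    "violin_data",
]


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1-based cluster id per spectrum
    k_chosen: int
    wcss_curve: pd.DataFrame  # columns: k, wcss
    seed: int
    n_init: int


def _matrix_values(matrix) -> np.ndarray:
    if isinstance(matrix, PeakMatrix):
        return np.asarray(matrix.values, dtype=float)
    return np.asarray(matrix, dtype=float)


def rms_normalize(matrix):
    """Divide each row by its root mean square, so every row has RMS 1.

    Zero rows are left zero with a warning.  Accepts and returns either a
    bare array or a PeakMatrix.
    """
    X = _matrix_values(matrix).copy()
    rms = np.sqrt(np.mean(X**2, axis=1))
    zero = rms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero row(s) left unnormalized")
        rms[zero] = 1.0
    X = X / rms[:, None]
    if isinstance(matrix, PeakMatrix):
        return PeakMatrix(
            values=X,
            spectrum_ids=list(matrix.spectrum_ids),
            feature_mz=matrix.feature_mz.copy(),
            mz_window=matrix.mz_window,
        )
    return X


def kmeans_partition(
    matrix,
    k_range=range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """k-means over a grid of cluster counts with WCSS-elbow selection.

    For each k the best of ``n_init`` k-means++ restarts is kept; the chosen
    k maximizes the second difference of the WCSS curve (the sharpest bend),
    so only interior grid points are eligible.  Labels are 1-based.
    """
    X = _matrix_values(matrix)
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values for elbow selection")
    if min(ks) < 2 or max(ks) > len(X) - 1:
        raise ValueError(f"k_range must lie within [2, n_rows-1] = [2, {len(X) - 1}]")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < max(ks):
        raise ValueError(
            f"only {n_distinct} distinct rows but k up to {max(ks)} requested"
        )
    fits, wcss = {}, []
    for k in ks:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
        km.fit(X)
        fits[k] = km
        wcss.append(float(km.inertia_))
    wcss = np.asarray(wcss)
    d2 = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]  # second difference at interior ks
    k_chosen = int(ks[1 + int(np.argmax(d2))])
    return ClusterResult(
        labels=fits[k_chosen].labels_ + 1,
        k_chosen=k_chosen,
        wcss_curve=pd.DataFrame({"k": ks, "wcss": wcss}),
        seed=seed,
        n_init=n_init,
    )


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) returning (U, p).

    Exact null distribution when both groups have ≤ 10 members; otherwise
    the normal approximation with tie correction.  Degenerate input where
    every value is identical gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not _has_ties(x, y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def marker_tests(matrix, labels, feature_mz: np.ndarray | None = None) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum per (cluster, feature), BH-corrected.

    Returns a long DataFrame with columns cluster, feature, feature_mz,
    stat, p, q, direction ('up' when the cluster's mean exceeds the rest).
    The BH correction runs across features within each cluster.  Singleton
    clusters are skipped with a warning.
    """
    X = _matrix_values(matrix)
    labels = np.asarray(labels)
    if feature_mz is None and isinstance(matrix, PeakMatrix):
        feature_mz = matrix.feature_mz
    rows = []
    for cl in np.unique(labels):
        inside = labels == cl
        if inside.sum() < 2:
            warnings.warn(f"cluster {cl} has fewer than 2 members; skipped")
            continue
        pvals, stats_u, direction = [], [], []
        for j in range(X.shape[1]):
            u, p = wilcoxon_rank_sum(X[inside, j], X[~inside, j])
            stats_u.append(u)
            pvals.append(p)
            direction.append("up" if X[inside, j].mean() > X[~inside, j].mean() else "down")
        q = multipletests(pvals, method="fdr_bh")[1]
        for j in range(X.shape[1]):
            rows.append(
                {
                    "cluster": cl,
                    "feature": j,
                    "feature_mz": float(feature_mz[j]) if feature_mz is not None else np.nan,
                    "stat": stats_u[j],
                    "p": pvals[j],
                    "q": float(q[j]),
                    "direction": direction[j],
                }
            )
    return pd.DataFrame(rows)


def violin_data(matrix, labels, feature_mz: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format RMS-normalized intensities for violin plots.

    Columns: cluster, feature_mz, norm_intensity — one row per
    (spectrum, feature) pair.
    """
    norm = rms_normalize(matrix)
    X = _matrix_values(norm)
    if feature_mz is None and isinstance(matrix, PeakMatrix):
        feature_mz = matrix.feature_mz
    labels = np.asarray(labels)
    n, m = X.shape
    return pd.DataFrame(
        {
            "cluster": np.repeat(labels, m),
            "feature_mz": np.tile(
                feature_mz if feature_mz is not None else np.arange(m), n
            ),
            "norm_intensity": X.ravel(),
        }
    )
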