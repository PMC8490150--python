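"""Deterministic CX decomposition for interpretable feature selection.

A spectra × features matrix A is approximated as A ≈ C X where C consists
of actual columns of A — concrete m/z features, not abstract eigenvectors.
Columns are ranked by their statistical leverage scores

    l_j = sum_{i=1}^{k} v_{ji}^2

over the top-k right singular vectors of A; the top-c columns form C and
X = argmin_X ||A - C X||_F is the least-squares coefficient matrix.  The
rank parameter k is chosen as the smallest rank whose best SVD
reconstruction error falls below a threshold (25% by default).

No centering or scaling is applied to A before the SVD: intensities are
nonnegative with zeros meaning "feature absent", and centering would
destroy that sparsity structure (a config switch is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CXResult", "RankSelection", "leverage_scores", "choose_rank", "cx_decompose"]


@dataclass
class CXResult:
    A_shape: tuple[int, int]
    k: int
    c: int
    leverage: np.ndarray  # per-column leverage scores, length n
    selected: np.ndarray  # indices of the top-c columns, in selection order
    X: np.ndarray  # (c, n) least-squares coefficients
    rel_error: float  # ||A - CX||_F / ||A||_F
    svd_rel_error_k: float  # best achievable rank-k relative error
    svd_rel_error_c: float  # best achievable rank-c relative error (a true
    # lower bound for rel_error, since C spans at most c dimensions; the
    # rank-k error bounds rel_error only when c <= k)

    def leverage_table(self, feature_mz: np.ndarray | None = None) -> pd.DataFrame:
        n = self.A_shape[1]
        sel = np.zeros(n, dtype=bool)
        sel[self.selected] = True
        d = {"leverage": self.leverage, "selected": sel}
        if feature_mz is not None:
            d = {"feature_mz": feature_mz, **d}
        return pd.DataFrame(d)


@dataclass
class RankSelection:
    k: int
    k_grid: np.ndarray
    errors: np.ndarray  # best rank-k relative Frobenius error per grid point
    satisfied: bool  # False when no k met the threshold


def _validate_k(A: np.ndarray, k: int) -> None:
    m, n = A.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"k must lie in [1, min(m, n)] = [1, {min(m, n)}], got {k}")


def leverage_scores(A: np.ndarray, k: int, center: bool = False) -> np.ndarray:
    """Per-column leverage from the top-k right singular vectors.

    Singular vectors are taken in descending singular-value order; the
    scores sum to k and each lies in [0, 1].
    """
    A = np.asarray(A, dtype=float)
    _validate_k(A, k)
    if center:
        A = A - A.mean(axis=0)
    _, _, Vt = np.linalg.svd(A, full_matrices=False)
    return np.sum(Vt[:k] ** 2, axis=0)


def choose_rank(
    A: np.ndarray,
    error_threshold: float = 0.25,
    k_grid: np.ndarray | None = None,
) -> RankSelection:
    """Smallest rank whose best SVD approximation error is below threshold.

    The best rank-k relative Frobenius error has the closed form
    sqrt(sum_{i>k} s_i^2 / sum_i s_i^2) in the singular values s_i, so the
    whole error curve costs one SVD.  If no grid rank satisfies the
    threshold, the largest is returned with a warning.
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    if k_grid is None:
        k_grid = np.arange(1, min(m, n) + 1)
    k_grid = np.asarray(k_grid, dtype=int)
    if len(k_grid) == 0 or np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be nonempty and strictly ascending")
    if k_grid[0] < 1 or k_grid[-1] > min(m, n):
        raise ValueError("k_grid entries must lie in [1, min(m, n)]")
    s = np.linalg.svd(A, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0:
        return RankSelection(k=int(k_grid[0]), k_grid=k_grid, errors=np.zeros(len(k_grid)), satisfied=True)
    tail = np.concatenate([np.cumsum((s**2)[::-1])[::-1], [0.0]])  # tail[k] = sum_{i>=k} s_i^2
    errors = np.sqrt(np.maximum(tail[k_grid], 0.0) / total)
    ok = errors < error_threshold
    if ok.any():
        k = int(k_grid[np.argmax(ok)])
        return RankSelection(k=k, k_grid=k_grid, errors=errors, satisfied=True)
    warnings.warn(
        f"no rank in the grid reaches relative error < {error_threshold}; "
        f"returning the largest (k={int(k_grid[-1])})"
    )
    return RankSelection(k=int(k_grid[-1]), k_grid=k_grid, errors=errors, satisfied=False)


def cx_decompose(A: np.ndarray, k: int, c: int = 200, center: bool = False) -> CXResult:
    """Select the top-c leverage columns and solve the least-squares X.

    Ties in leverage are broken toward the lower column index, for
    reproducibility.  ``rel_error`` is never below the best rank-k SVD
    error; it reaches zero when c = n (C spans all of A's columns).
    """
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    _validate_k(A, k)
    if not (1 <= c <= n):
        raise ValueError(f"c must lie in [1, n] = [1, {n}], got {c}")
    work = A - A.mean(axis=0) if center else A
    _, s, Vt = np.linalg.svd(work, full_matrices=False)
    lev = np.sum(Vt[:k] ** 2, axis=0)
    # descending leverage, ties to the lower index
    order = np.lexsort((np.arange(n), -lev))
    selected = order[:c]
    C = A[:, selected]
    X = np.linalg.pinv(C) @ A
    normA = np.linalg.norm(A)
    rel = float(np.linalg.norm(A - C @ X) / normA) if normA > 0 else 0.0
    total = float(np.sum(s**2))

    def _svd_err(rank: int) -> float:
        if total == 0:
            return 0.0
        return float(np.sqrt(max(np.sum((s**2)[rank:]), 0.0) / total))

    return CXResult(
        A_shape=(m, n),
        k=k,
        c=c,
        leverage=lev,
        selected=selected,
        X=X,
        rel_error=rel,
        svd_rel_error_k=_svd_err(k),
        svd_rel_error_c=_svd_err(min(c, len(s))),
    )
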