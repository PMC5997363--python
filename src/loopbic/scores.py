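"""Uncorrected loop-scores, the d-score family and the spectral comparator.

A loop is a 2x2 submatrix of a sign matrix D; it is rank-1 when the product of
its four entries is +1 and rank-2 when the product is -1. The row loop-score
tallies rank-1 minus rank-2 loops through each row; in matrix form it is a
diagonal entry of (D D^T)^2, and the column score a diagonal entry of
(D^T D)^2. Generalizing the path length gives d-scores diag((D D^T)^(d+1)),
which converge (after normalization) to the entrywise squares of the leading
singular vectors — the simple spectral method at d = infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import check_sign
from . import bruteforce

__all__ = ["ScorePair", "ScoreConfig", "loop_scores", "loop_scores_bruteforce", "d_scores", "spectral_scores"]


@dataclass
class ScorePair:
    """Row scores (length M) and column scores (length N) of one matrix."""

    z_row: np.ndarray
    z_col: np.ndarray
    normalized: bool = False
    extras: dict = field(default_factory=dict)


@dataclass
class ScoreConfig:
    """Knobs shared by the iterative pipelines.

    d        path-depth parameter: 1 = loop-score, None/inf = spectral
    gamma    fraction of the remaining rows/columns eliminated per iteration
    seed     master seed for any randomized step
    """

    d: int = 1
    gamma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.d is not None and self.d < 1:
            raise ValueError("d must be >= 1")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")


def loop_scores(D, normalized: bool = False) -> ScorePair:
    """Row/column loop-scores of a sign matrix.

    Raw form (default): z_row = diag(D D^T D D^T), z_col = diag(D^T D D^T D),
    exact integers; the sums include the degenerate loops with repeated row or
    column. With ``normalized=True`` the degenerate loops are removed and the
    sum is divided by its number of summands, giving scores in [-1, 1] that are
    comparable across matrix sizes (the form the corrected scores build on).
    """
    A = check_sign(D)
    m, n = A.shape
    G = (A @ A.T).astype(np.int64) if A.size <= 10**7 else A @ A.T
    H = (A.T @ A).astype(np.int64) if A.size <= 10**7 else A.T @ A
    z_row = np.einsum("ij,ij->i", G, G)
    z_col = np.einsum("ij,ij->i", H, H)
    if not normalized:
        return ScorePair(np.asarray(z_row), np.asarray(z_col), normalized=False)
    if m < 2 or n < 2:
        raise ValueError("normalized loop-scores need at least 2 rows and 2 columns")
    zr = (z_row - n * (n + m - 1)) / ((m - 1) * n * (n - 1))
    zc = (z_col - m * (m + n - 1)) / ((n - 1) * m * (m - 1))
    return ScorePair(zr, zc, normalized=True)


def loop_scores_bruteforce(D, exclude_degenerate: bool = False) -> ScorePair:
    """Loop-scores by explicit enumeration of every (j, j', k, k') quadruple.

    Definitional oracle for :func:`loop_scores`; O(M^2 N^2) memory and time.
    """
    A = check_sign(D)
    # the raw score counts loops with repeated rows/columns too, so the j' = j
    # terms are masked only when the degenerate loops are excluded
    zr = bruteforce.row_quadruple_sum(A, A, exclude_degenerate=exclude_degenerate, same=exclude_degenerate)
    zc = bruteforce.col_quadruple_sum(A, A, exclude_degenerate=exclude_degenerate, same=exclude_degenerate)
    return ScorePair(zr, zc, normalized=False)


def d_scores(D, d: int, rescale: bool = False) -> ScorePair:
    """Signed closed-path tallies of length 2d+2: diag((D D^T)^(d+1)).

    d = 1 reproduces the loop-scores. With ``rescale`` each matrix power is
    divided by its largest entry to avoid overflow for large d (scores are then
    meaningful only up to a positive factor, which is all ranking needs).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    A = check_sign(D)

    def _diag_power(G, k):
        P = G.copy()
        for _ in range(k - 1):
            P = P @ G
            if rescale:
                P /= np.abs(P).max()
        return np.diagonal(P).copy()

    return ScorePair(
        _diag_power(A @ A.T, d + 1),
        _diag_power(A.T @ A, d + 1),
        normalized=False,
        extras={"d": d},
    )


def spectral_scores(D, tie_tol: float = 1e-8) -> ScorePair:
    """Entrywise squares of the leading singular vectors; each sums to 1.

    At a degenerate leading singular value (sigma1 - sigma2 < tie_tol*sigma1,
    where the leading vector is not well defined) the diagonal of the projector
    onto the tied subspace is used, rescaled to sum to 1 — a deterministic,
    basis-independent tie-break.
    """
    A = check_sign(D)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    k = 1
    while k < s.size and (s[0] - s[k]) < tie_tol * s[0]:
        k += 1
    z_row = (U[:, :k] ** 2).sum(axis=1) / k
    z_col = (Vt[:k, :] ** 2).sum(axis=0) / k
    return ScorePair(z_row, z_col, normalized=True, extras={"n_tied": k})
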