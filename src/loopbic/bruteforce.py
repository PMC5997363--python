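"""Brute-force loop-sum oracles.

Every score in this package is a (possibly weighted) sum over explicit loops —
quadruples (j, j', k, k') of two rows and two columns. The production code
evaluates those sums with Gram products; the functions here instead construct
the full 4-index tensor of loop terms by broadcasting and reduce it under
explicit masks. They share no algebra with the fast path, and are only
feasible for small matrices (O(M^2 N^2) memory); they exist to pin down the
definitions and to certify the fast implementations, exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "loop_term_tensor",
    "row_quadruple_sum",
    "col_quadruple_sum",
    "oracle_control_scores",
    "oracle_categorical_row",
    "oracle_categorical_col",
    "oracle_continuous_scores",
    "oracle_sparsity_scores",
    "oracle_tri_scores",
]


def _prep(A, B, alpha, delta):
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    n = A.shape[1]
    if alpha is None:
        Ca, Cb = A, B
    else:
        alpha = np.asarray(alpha, dtype=np.float64)
        Ca, Cb = A - alpha, B - alpha
    d = np.ones(n) if delta is None else np.asarray(delta, dtype=np.float64)
    return Ca, Cb, d


def loop_term_tensor(A, B, alpha=None, delta=None) -> np.ndarray:
    """T[j, J, k, K] = Ca[j,k] d_k Cb[J,k] Cb[J,K] d_K Ca[j,K].

    One entry per loop through rows (j in A, J in B) and columns (k, K),
    with optional column centering (``alpha``) and diagonal weights
    (``delta``). Rows and columns are scored by reducing this tensor over
    different axes.
    """
    Ca, Cb, d = _prep(A, B, alpha, delta)
    return np.einsum("jk,Jk,JK,jK,k,K->jJkK", Ca, Cb, Cb, Ca, d, d)


def _masked_reduce(T, same: bool, exclude_degenerate: bool, axis: str, wa=None, wb=None):
    ma, mb, n, _ = T.shape
    W = T
    if wa is not None:
        W = W * np.asarray(wa, dtype=np.float64)[:, None, None, None]
    if wb is not None:
        W = W * np.asarray(wb, dtype=np.float64)[None, :, None, None]
    mask = np.ones_like(W, dtype=bool)
    if same:
        if ma != mb:
            raise ValueError("same=True requires matching row populations")
        jj = np.eye(ma, dtype=bool)
        mask &= ~jj[:, :, None, None]
    if exclude_degenerate:
        kk = np.eye(n, dtype=bool)
        mask &= ~kk[None, None, :, :]
    W = np.where(mask, W, 0.0)
    if axis == "row":
        out = W.sum(axis=(1, 2, 3))
        count = (mb - int(same)) * n * (n - 1 if exclude_degenerate else n)
    else:
        out = W.sum(axis=(0, 1, 3))
        count = ma * (mb - int(same)) * (n - 1 if exclude_degenerate else n)
    return out, count


def row_quadruple_sum(A, B, *, same, exclude_degenerate=True, alpha=None, delta=None,
                      wa=None, wb=None, normalized=False):
    """Per-row-of-A loop sum against partner rows B; optional row weights."""
    T = loop_term_tensor(A, B, alpha, delta)
    out, count = _masked_reduce(T, same, exclude_degenerate, "row", wa, wb)
    return out / count if normalized else out


def col_quadruple_sum(A, B, *, same, exclude_degenerate=True, alpha=None, delta=None,
                      wa=None, wb=None, normalized=False):
    """Per-column loop sum with one row drawn from A and one from B."""
    T = loop_term_tensor(A, B, alpha, delta)
    out, count = _masked_reduce(T, same, exclude_degenerate, "col", wa, wb)
    return out / count if normalized else out


# ---------------------------------------------------------------- corrected


def oracle_control_scores(D, X):
    """Control-corrected scores: normalized within-case sum minus case/control sum."""
    zr = (row_quadruple_sum(D, D, same=True, normalized=True)
          - row_quadruple_sum(D, X, same=False, normalized=True))
    zc = (col_quadruple_sum(D, D, same=True, normalized=True)
          - col_quadruple_sum(D, X, same=False, normalized=True))
    return zr, zc


def oracle_categorical_row(D1, D2):
    """Two-category row scores, printed scale: min(Z1/p, Z2/q) per patient.

    Returns the scores for the rows of D1 followed by the rows of D2.
    """
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    m1, m2 = D1.shape[0], D2.shape[0]
    m = m1 + m2
    out = []
    for (Da, Db, ma, mb) in ((D1, D2, m1, m2), (D2, D1, m2, m1)):
        z1 = row_quadruple_sum(Da, Da, same=True)
        z2 = row_quadruple_sum(Da, Db, same=False)
        p = (ma - 1) / (m - 1)
        q = mb / (m - 1)
        out.append(np.minimum(z1 / p, z2 / q))
    return np.concatenate(out)


def oracle_categorical_col(D1, D2):
    """Two-category column scores, printed scale: four-way normalized min."""
    D1 = np.asarray(D1, float)
    D2 = np.asarray(D2, float)
    m1, m2 = D1.shape[0], D2.shape[0]
    m = m1 + m2
    mbar2 = m * m - m1 - m2
    a11 = m1 * (m1 - 1) / mbar2
    a12 = a21 = m1 * m2 / mbar2
    a22 = m2 * (m2 - 1) / mbar2
    z11 = col_quadruple_sum(D1, D1, same=True)
    z12 = col_quadruple_sum(D1, D2, same=False)
    z21 = col_quadruple_sum(D2, D1, same=False)
    z22 = col_quadruple_sum(D2, D2, same=True)
    return np.minimum.reduce([z11 / a11, z12 / a12, z21 / a21, z22 / a22])


def oracle_continuous_scores(D, T, kappa2):
    """Continuous-covariate-corrected scores from explicit weighted loop sums.

    Returns (z_row_sq, z_col): the squared row score (sign kept) and the
    column score, exactly as the printed formulas define them.
    """
    D = np.asarray(D, float)
    T = np.asarray(T, float)
    nt = T.shape[1]
    base_r = row_quadruple_sum(D, D, same=True, normalized=True)
    base_c = col_quadruple_sum(D, D, same=True, normalized=True)
    zt_r = np.stack([
        row_quadruple_sum(D, D, same=True, wa=T[:, t], wb=T[:, t], normalized=True)
        for t in range(nt)
    ])
    zt_c = np.stack([
        col_quadruple_sum(D, D, same=True, wa=T[:, t], wb=T[:, t], normalized=True)
        for t in range(nt)
    ])
    z_row_sq = np.maximum(base_r, 0.0) ** 2 - (np.maximum(zt_r, 0.0) ** 2).mean(axis=0) / kappa2
    z_col = base_c - zt_c.mean(axis=0) / kappa2
    return z_row_sq, z_col


def oracle_sparsity_scores(D, profile):
    """Sparsity-corrected scores via centered, delta-weighted loop tensors."""
    D = np.asarray(D, float)
    zr = row_quadruple_sum(D, D, same=True, alpha=profile.alpha, delta=profile.delta,
                           normalized=True)
    zc = col_quadruple_sum(D, D, same=True, alpha=profile.alpha, delta=profile.delta,
                           normalized=True)
    return zr, zc


# ---------------------------------------------------------------- tricluster


def oracle_tri_scores(cube):
    """Row/column/layer scores of a sign cube by explicit 5-index tensors.

    Each score adds two normalized constituent sums over the two loop
    categories that touch the scored axis (iso-layer, iso-column, iso-row).
    """
    C = np.asarray(cube, dtype=np.float64)
    mj, mk, ml = C.shape
    ej = ~np.eye(mj, dtype=bool)
    ek = ~np.eye(mk, dtype=bool)
    el = ~np.eye(ml, dtype=bool)

    # iso-layer loops: rows j,J and columns k,K within one layer l
    iso_layer = np.einsum("jkl,Jkl,JKl,jKl->jJkKl", C, C, C, C)
    iso_layer = iso_layer * ej[:, :, None, None, None] * ek[None, None, :, :, None]
    # iso-column loops: rows j,J and layers l,L within one column k
    iso_col = np.einsum("jkl,Jkl,JkL,jkL->jJklL", C, C, C, C)
    iso_col = iso_col * ej[:, :, None, None, None] * el[None, None, None, :, :]
    # iso-row loops: columns k,K and layers l,L within one row j
    iso_row = np.einsum("jkl,jKl,jKL,jkL->jkKlL", C, C, C, C)
    iso_row = iso_row * ek[None, :, :, None, None] * el[None, None, None, :, :]

    n_lay_row = (mj - 1) * mk * (mk - 1) * ml
    n_col_row = (mj - 1) * ml * (ml - 1) * mk
    z_row = iso_layer.sum(axis=(1, 2, 3, 4)) / n_lay_row + iso_col.sum(axis=(1, 3, 4, 2)) / n_col_row

    n_lay_col = mj * (mj - 1) * (mk - 1) * ml
    n_row_col = mj * (mk - 1) * ml * (ml - 1)
    z_col = iso_layer.sum(axis=(0, 1, 3, 4)) / n_lay_col + iso_row.sum(axis=(0, 2, 3, 4)) / n_row_col

    n_col_lyr = mj * (mj - 1) * (ml - 1) * mk
    n_row_lyr = mj * mk * (mk - 1) * (ml - 1)
    z_lyr = iso_col.sum(axis=(0, 1, 2, 4)) / n_col_lyr + iso_row.sum(axis=(0, 1, 2, 4)) / n_row_lyr

    return z_row, z_col, z_lyr
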