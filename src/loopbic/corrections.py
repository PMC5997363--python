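"""Corrected loop-scores: controls, covariates, sparsity, and their combination.

All corrections reweight or re-sign the same underlying quantity: normalized
sums of loop terms over quadruples (j, j', k, k') with the degenerate loops
(j' = j or k' = k) removed. Sums are evaluated with Gram products, never by
loop enumeration (the enumerating oracle lives in :mod:`loopbic.bruteforce`).
Throughout, a "normalized sum" divides by its number of summands, so every
normalized score of a +/-1 matrix lies in [-1, 1] and a difference of two such
terms (the control correction) lies in [-2, 2].

Corrections compose in a fixed order — sparsity, continuous covariates,
categorical covariates, cases-versus-controls — see :func:`combined_scores`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import check_sign, derive_rng
from .preprocess import SparsityProfile
from .scores import ScorePair

__all__ = [
    "ControlSplit",
    "CategoricalDesign",
    "ContinuousCovariates",
    "control_scores",
    "categorical_scores",
    "continuous_scores",
    "kappa_squared",
    "sparsity_scores",
    "combined_scores",
]


# ----------------------------------------------------------------- designs


@dataclass
class ControlSplit:
    """Case matrix D (M_D x N) and control matrix X (M_X x N), same columns."""

    D: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        self.D = check_sign(self.D)
        self.X = check_sign(self.X)
        if self.D.shape[1] != self.X.shape[1]:
            raise ValueError("cases and controls must share the same columns")
        if self.D.shape[0] < 2 or self.D.shape[1] < 2:
            raise ValueError("need at least 2 case rows and 2 columns")
        if self.X.shape[0] < 1:
            raise ValueError("need at least 1 control row")


@dataclass
class CategoricalDesign:
    """Per-patient category labels plus the straddling requirement I_req.

    ``i_req`` is the number of categories a bicluster is required to straddle;
    the row/column scores keep only the best ``i_req`` categories and take the
    minimum over them, so a structure concentrated in fewer than ``i_req``
    categories is demoted. With two categories and i_req = 2 this reduces to
    the exact two-category formulas.
    """

    labels: np.ndarray
    i_req: int = 2

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.categories = [c for c in dict.fromkeys(self.labels.tolist())]
        if not (2 <= self.i_req <= max(2, len(self.categories))):
            raise ValueError("need 2 <= i_req <= number of categories")

    def groups(self):
        return {c: np.flatnonzero(self.labels == c) for c in self.categories}


@dataclass
class ContinuousCovariates:
    """M x N_T continuous covariates (e.g. mds-components), one row per patient.

    Rows are normalized to unit length so that the attenuation constant
    kappa^2 depends only on the covariate dimension N_T; all-zero rows are
    left at zero (they contribute no covariate signal). ``kappa2`` may be
    given; otherwise it is estimated once by :func:`kappa_squared`.
    """

    T: np.ndarray
    kappa2: float | None = None
    _kappa_n_mc: int = field(default=100_000, repr=False)
    _kappa_seed: int = field(default=0, repr=False)

    def __post_init__(self):
        T = np.asarray(self.T, dtype=np.float64)
        if T.ndim != 2:
            raise ValueError("covariates must be a 2-D (patients x N_T) array")
        norms = np.linalg.norm(T, axis=1, keepdims=True)
        self.T = np.divide(T, norms, out=np.zeros_like(T), where=norms > 0)

    @property
    def n_t(self) -> int:
        return self.T.shape[1]

    def resolve_kappa2(self) -> float:
        if self.kappa2 is None:
            self.kappa2 = kappa_squared(self.n_t, n_mc=self._kappa_n_mc, seed=self._kappa_seed)
        return float(self.kappa2)

    def subset(self, rows) -> "ContinuousCovariates":
        sub = ContinuousCovariates(self.T[np.asarray(rows)], kappa2=self.kappa2)
        return sub


# ------------------------------------------------------------ loop kernels


def _loop_mats(Ca, Cb, delta=None):
    """E[j,J] = sum_k Ca[j,k] d_k Cb[J,k] and the k'!=k pair matrix Q.

    Q[j,J] = sum over ordered column pairs (k, K), K != k, of the weighted
    loop term Ca[j,k] d_k Cb[J,k] Cb[J,K] d_K Ca[j,K] — i.e. E^2 with the
    K = k diagonal terms removed.
    """
    d = np.ones(Ca.shape[1]) if delta is None else delta
    P = Ca * d
    E = P @ Cb.T
    F = (P * P) @ (Cb * Cb).T
    return E, E * E - F


def _col_sums(Ca, Cb, E, delta=None, wa=None, wb=None, same=False):
    """Per-column loop sums with one row from each population.

    sum over (j in a, J in b [J != j if same], K != k) of
    wa_j wb_J * Ca[j,k] d_k Cb[J,k] * Ca[j,K] d_K Cb[J,K].
    """
    d = np.ones(Ca.shape[1]) if delta is None else delta
    P = Ca * d
    R = Cb
    wa_ = np.ones(Ca.shape[0]) if wa is None else np.asarray(wa, float)
    wb_ = np.ones(Cb.shape[0]) if wb is None else np.asarray(wb, float)
    A1 = np.einsum("jk,jJ,Jk->k", P * wa_[:, None], E, R * wb_[:, None])
    A2 = ((P * P) * wa_[:, None]).sum(0) * ((R * R) * wb_[:, None]).sum(0)
    out = A1 - A2
    if same:
        diag = np.diagonal(E)
        PR = P * R
        out = out - ((wa_ * wb_)[:, None] * PR * (diag[:, None] - PR)).sum(0)
    return out


def _row_count(mb, n, same):
    return (mb - int(same)) * n * (n - 1)


def _col_count(ma, mb, n, same):
    return (ma * mb - int(same) * ma) * (n - 1)


# ---------------------------------------------------------------- controls


def control_scores(split: ControlSplit | None = None, D=None, X=None) -> ScorePair:
    """Control-corrected scores: within-case minus case/control loop terms.

    Row j:  Z_ROW^DD_j - Z_ROW^DX_j with
      Z_ROW^DD_j = ([D D^T D D^T]_jj - N(N + M_D - 1)) / ((M_D - 1) N (N-1))
      Z_ROW^DX_j = ([D X^T X D^T]_jj - M_X N)          / (M_X N (N-1))
    and the analogous column form. Both terms are normalized loop sums in
    [-1, 1], so every score lies in [-2, 2]. A bicluster that straddles cases
    and controls equally scores ~0; a fully case-specific one scores as it
    would uncorrected.
    """
    if split is None:
        split = ControlSplit(D, X)
    Dm, Xm = split.D, split.X
    md, n = Dm.shape
    mx = Xm.shape[0]
    _, Qdd = _loop_mats(Dm, Dm)
    _, Qdx = _loop_mats(Dm, Xm)
    z_row = ((Qdd.sum(1) - np.diagonal(Qdd)) / _row_count(md, n, True)
             - Qdx.sum(1) / _row_count(mx, n, False))
    Edd, _ = _loop_mats(Dm, Dm)
    Edx, _ = _loop_mats(Dm, Xm)
    z_col = (_col_sums(Dm, Dm, Edd, same=True) / _col_count(md, md, n, True)
             - _col_sums(Dm, Xm, Edx, same=False) / _col_count(md, mx, n, False))
    return ScorePair(z_row, z_col, normalized=True)


# ------------------------------------------------------------- categorical


def _cat_row_terms(blocks):
    """Unnormalized within/cross row loop sums; terms[a][b] is a vector over rows of block a."""
    n = blocks[0].shape[1]
    terms = []
    for a, Da in enumerate(blocks):
        row_terms = []
        for b, Db in enumerate(blocks):
            _, Q = _loop_mats(Da, Db)
            if a == b:
                row_terms.append(Q.sum(1) - np.diagonal(Q))
            else:
                row_terms.append(Q.sum(1))
        terms.append(row_terms)
    return terms


def categorical_scores(blocks, i_req: int = 2, normalized: bool = False) -> ScorePair:
    """Categorical-covariate-corrected scores over category blocks D1, D2, ...

    Two categories (the exact printed case): for a patient in block a,
    z_row = min(Z_within / p, Z_cross / q) with p = (M_a - 1)/(M - 1) and
    q = M_b/(M - 1); columns take the minimum of the four within/cross sums
    ZCOL_ab / alpha_ab with alpha_ab = M_a (M_b - delta_ab) / (M^2 - M).
    More categories generalize by keeping the best ``i_req`` categories and
    taking the minimum over them (rows) / over their pairs (columns); this is
    a documented generalization of the two-category formulas.

    Rows are returned in block concatenation order. With ``normalized`` the
    row scores are divided by (M-1) N (N-1) and the column scores by
    (N-1)(M^2 - M), putting them on the [-1, 1] per-loop scale.
    """
    blocks = [check_sign(b) for b in blocks]
    if len(blocks) < 2:
        raise ValueError("need at least two category blocks")
    n = blocks[0].shape[1]
    if any(b.shape[1] != n for b in blocks):
        raise ValueError("all blocks must share the same columns")
    if any(b.shape[0] < 2 for b in blocks):
        raise ValueError("every category needs at least 2 patients for its within-category terms")
    sizes = [b.shape[0] for b in blocks]
    m = sum(sizes)
    i_req = min(i_req, len(blocks))

    # rows: per-category fractions p (within) and q_b (cross)
    row_terms = _cat_row_terms(blocks)
    z_row_parts = []
    for a, Da in enumerate(blocks):
        vals = []
        for b in range(len(blocks)):
            frac = (sizes[a] - 1) / (m - 1) if a == b else sizes[b] / (m - 1)
            vals.append(row_terms[a][b] / frac)
        vals = np.stack(vals)  # (n_cat, rows of block a)
        top = np.sort(vals, axis=0)[::-1][:i_req]
        z_row_parts.append(top.min(axis=0))
    z_row = np.concatenate(z_row_parts)

    # columns: per ordered category pair
    mbar2 = m * m - m
    pair_vals = {}
    for a, Da in enumerate(blocks):
        for b, Db in enumerate(blocks):
            E, _ = _loop_mats(Da, Db)
            s = _col_sums(Da, Db, E, same=(a == b))
            alpha = sizes[a] * (sizes[b] - (1 if a == b else 0)) / mbar2
            pair_vals[(a, b)] = s / alpha
    per_cat_best = {a: np.maximum.reduce([pair_vals[(a, b)] for b in range(len(blocks))])
                    for a in range(len(blocks))}
    # rank categories per column by their best pair term, keep top i_req
    stack_best = np.stack([per_cat_best[a] for a in range(len(blocks))])  # (n_cat, N)
    order = np.argsort(-stack_best, axis=0, kind="mergesort")[:i_req]  # categories kept, per column
    z_col = np.full(n, np.inf)
    for a in range(len(blocks)):
        for b in range(len(blocks)):
            active = np.any(order == a, axis=0) & np.any(order == b, axis=0)
            z_col = np.where(active, np.minimum(z_col, pair_vals[(a, b)]), z_col)

    if normalized:
        z_row = z_row / ((m - 1) * n * (n - 1))
        z_col = z_col / ((n - 1) * mbar2)
    return ScorePair(z_row, z_col, normalized=normalized)


# -------------------------------------------------------------- continuous


def kappa_squared(n_t: int, n_mc: int = 100_000, seed: int = 0, ensemble: str = "simplex") -> float:
    """Attenuation constant for the continuous-covariate correction.

    Operational definition: the average, over random fully
    covariate-concentrated configurations (all patients of a rank-1 bicluster
    sharing one unit covariate vector u), of the covariate-averaged loop-score
    of that bicluster. For a shared direction the per-dimension weighted score
    is Z[t] = u_t^2, so the attenuation is mean_t u_t^4, and dividing by
    kappa^2 restores the covariate-averaged score to the base score on
    average — which is exactly what lets the correction demote concentrated
    biclusters to zero while leaving dispersed ones untouched.

    The default ensemble draws the squared components u_t^2 uniformly from the
    probability simplex: every split of covariate energy across the N_T
    dimensions is equally likely, which treats an axis-aligned concentration
    and a diagonal one symmetrically. For N_T = 2 this gives kappa^2 = 1/3
    (approximately 0.34); for N_T = 1 it gives exactly 1 (a single unit weight
    attenuates nothing). ``ensemble="sphere"`` instead draws u uniformly on
    the unit sphere (kappa^2 = 3/(N_T (N_T+2)), e.g. 0.375 for N_T = 2).
    """
    if n_t < 1:
        raise ValueError("n_t must be >= 1")
    if n_mc < 1000:
        warnings.warn("n_mc < 1000 gives a high-variance kappa^2 estimate", stacklevel=2)
    rng = derive_rng(seed, 0xCA)
    if ensemble == "simplex":
        sq = rng.dirichlet(np.ones(n_t), size=n_mc)
    elif ensemble == "sphere":
        g = rng.standard_normal((n_mc, n_t))
        u = g / np.linalg.norm(g, axis=1, keepdims=True)
        sq = u * u
    else:
        raise ValueError(f"unknown ensemble {ensemble!r}")
    return float((sq * sq).mean(axis=1).mean())


def _continuous_row(base, zt, kappa2):
    """Signed-square row combination: z^2 = floor(base)^2 - mean_t floor(Z[t])^2 / kappa^2.

    Returns (z, z_sq) where z = sign(z^2) sqrt|z^2| keeps the score on the
    same per-loop scale as the other corrections.
    """
    z_sq = np.maximum(base, 0.0) ** 2 - (np.maximum(zt, 0.0) ** 2).mean(axis=0) / kappa2
    return np.sign(z_sq) * np.sqrt(np.abs(z_sq)), z_sq


def continuous_scores(D, cov: ContinuousCovariates) -> ScorePair:
    """Continuous-covariate-corrected scores.

    Rows: the base loop sum is floored and squared, and the per-dimension
    covariate-weighted sums Z[t] (each loop term multiplied by T_jt T_j't) are
    floored, squared, averaged over t and divided by kappa^2 before
    subtraction; the returned row score is the signed square root (the squared
    form is in ``extras["z_row_sq"]``). Columns subtract the covariate-
    averaged term linearly, exactly as printed, with no floor or square.
    """
    A = check_sign(D)
    m, n = A.shape
    if cov.T.shape[0] != m:
        raise ValueError("covariate rows must match matrix rows")
    kappa2 = cov.resolve_kappa2()
    T = cov.T
    E, Q = _loop_mats(A, A)
    rc = _row_count(m, n, True)
    cc = _col_count(m, m, n, True)
    base_r = (Q.sum(1) - np.diagonal(Q)) / rc
    base_c = _col_sums(A, A, E, same=True) / cc
    zt_r = np.stack([
        T[:, t] * (Q @ T[:, t] - np.diagonal(Q) * T[:, t]) / rc for t in range(cov.n_t)
    ])
    zt_c = np.stack([
        _col_sums(A, A, E, wa=T[:, t], wb=T[:, t], same=True) / cc for t in range(cov.n_t)
    ])
    z_row, z_row_sq = _continuous_row(base_r, zt_r, kappa2)
    z_col = base_c - zt_c.mean(axis=0) / kappa2
    return ScorePair(z_row, z_col, normalized=True,
                     extras={"z_row_sq": z_row_sq, "kappa2": kappa2})


# ---------------------------------------------------------------- sparsity


def sparsity_scores(D, prof: SparsityProfile) -> ScorePair:
    """Sparsity-corrected scores: columns centered by alpha_k and loops
    weighted by delta_k = 1/(4 p_k q_k), so abundant signs contribute little
    and rare ones more. At p_k = 1/2 everywhere this reduces exactly to the
    normalized uncorrected loop-score.
    """
    A = check_sign(D)
    m, n = A.shape
    if prof.p.shape[0] != n:
        raise ValueError("sparsity profile must match matrix columns")
    C = A - prof.alpha
    E, Q = _loop_mats(C, C, prof.delta)
    z_row = (Q.sum(1) - np.diagonal(Q)) / _row_count(m, n, True)
    z_col = _col_sums(C, C, E, delta=prof.delta, same=True) / _col_count(m, m, n, True)
    return ScorePair(z_row, z_col, normalized=True)


# ---------------------------------------------------------------- combined


def combined_scores(D, X=None, design: CategoricalDesign | None = None,
                    cov: ContinuousCovariates | None = None,
                    prof: SparsityProfile | None = None) -> ScorePair:
    """All corrections in one normalized scoring pass.

    Order of composition (fixed): (1) sparsity — columns are centered and
    delta-weighted in every loop term; (2) continuous covariates — each
    case-side term is covariate-corrected (signed-square rows, linear
    columns); (3) categorical covariates — case-side terms are computed per
    category (rows) / category pair (columns) and the minimum over the best
    i_req categories is taken; (4) controls — the normalized case/control
    term is subtracted. With everything disabled this is exactly the
    normalized uncorrected loop-score.

    The control term is not covariate-corrected (demoting it would inflate
    the final score) and pools all control rows regardless of category.
    Per-stage components are exposed in ``extras`` for debugging.
    """
    A = check_sign(D)
    m, n = A.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    alpha = prof.alpha if prof is not None else None
    delta = prof.delta if prof is not None else None
    Ca = A - alpha if alpha is not None else A
    kappa2 = cov.resolve_kappa2() if cov is not None else None
    T = cov.T if cov is not None else None
    if T is not None and T.shape[0] != m:
        raise ValueError("covariate rows must match case rows")

    E, Q = _loop_mats(Ca, Ca, delta)
    diagQ = np.diagonal(Q)

    groups = design.groups() if design is not None else {None: np.arange(m)}
    group_items = [(c, idx) for c, idx in groups.items() if idx.size > 0]
    i_req = min(design.i_req, len(group_items)) if design is not None else 1

    # ---- rows: per-partner-group corrected terms, then categorical min
    def row_term(idx):
        """Normalized (and covariate-corrected) loop sum of every row against
        partner rows idx; rows inside idx exclude themselves."""
        inside = np.zeros(m, dtype=bool)
        inside[idx] = True
        cnt = np.where(inside, idx.size - 1, idx.size) * n * (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            base = (Q[:, idx].sum(1) - np.where(inside, diagQ, 0.0)) / cnt
        if T is None:
            return base
        zt = np.stack([
            T[:, t] * (Q[:, idx] @ T[idx, t] - np.where(inside, diagQ * T[:, t], 0.0)) / cnt
            for t in range(T.shape[1])
        ])
        z, _ = _continuous_row(base, zt, kappa2)
        return z

    terms = []
    for c, idx in group_items:
        if idx.size >= 2:
            terms.append(row_term(idx))
        else:
            terms.append(np.full(m, np.nan))  # singleton category: no within term
    terms = np.stack(terms)  # (n_groups, m); nan where undefined
    if design is None:
        case_row = terms[0]
    else:
        vals = np.where(np.isnan(terms), -np.inf, terms)
        top = np.sort(vals, axis=0)[::-1][:i_req]
        case_row = top.min(axis=0)
        case_row = np.where(np.isfinite(case_row), case_row, np.nan)

    # ---- columns: per category-pair corrected terms, then min over pairs
    def col_term(ia, ib, same):
        Caa, Cbb = Ca[ia], Ca[ib]
        Eab, _ = _loop_mats(Caa, Cbb, delta)
        cnt = _col_count(ia.size, ib.size, n, same)
        base = _col_sums(Caa, Cbb, Eab, delta=delta, same=same) / cnt
        if T is None:
            return base
        zt = np.stack([
            _col_sums(Caa, Cbb, Eab, delta=delta, wa=T[ia, t], wb=T[ib, t], same=same) / cnt
            for t in range(T.shape[1])
        ])
        return base - zt.mean(axis=0) / kappa2

    if design is None:
        case_col = col_term(np.arange(m), np.arange(m), True)
    else:
        pair_vals = {}
        for a, (ca, ia) in enumerate(group_items):
            for b, (cb, ib) in enumerate(group_items):
                if a == b and ia.size < 2:
                    continue
                pair_vals[(a, b)] = col_term(ia, ib, a == b)
        best = np.stack([
            np.maximum.reduce([v for (a, b), v in pair_vals.items() if a == g] or [np.full(n, -np.inf)])
            for g in range(len(group_items))
        ])
        order = np.argsort(-best, axis=0, kind="mergesort")[:i_req]
        case_col = np.full(n, np.inf)
        for (a, b), v in pair_vals.items():
            active = np.any(order == a, axis=0) & np.any(order == b, axis=0)
            case_col = np.where(active, np.minimum(case_col, v), case_col)

    extras = {"case_row": case_row.copy(), "case_col": case_col.copy()}

    # ---- controls
    if X is not None:
        Xm = check_sign(X)
        if Xm.shape[1] != n:
            raise ValueError("controls must share the case columns")
        Cx = Xm - alpha if alpha is not None else Xm
        Ex, Qx = _loop_mats(Ca, Cx, delta)
        ctrl_row = Qx.sum(1) / _row_count(Xm.shape[0], n, False)
        ctrl_col = _col_sums(Ca, Cx, Ex, delta=delta, same=False) / _col_count(m, Xm.shape[0], n, False)
        extras["control_row"] = ctrl_row
        extras["control_col"] = ctrl_col
        z_row = case_row - ctrl_row
        z_col = case_col - ctrl_col
    else:
        z_row, z_col = case_row, case_col

    if kappa2 is not None:
        extras["kappa2"] = kappa2
    return ScorePair(z_row, z_col, normalized=True, extras=extras)
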