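"""Iterative row/column elimination and bicluster delineation.

The dominant bicluster is found by repeatedly scoring the remaining submatrix
and discarding the lowest-scoring fraction gamma of rows and columns. Members
of a coherent low-rank block reinforce each other's scores and survive long;
the output is therefore an *ordering* of rows and columns by elimination time,
plus per-iteration traces (mean scores before each removal) whose peak marks
the iteration at which the bicluster dominated the remaining submatrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import check_sign, derive_rng
from .corrections import CategoricalDesign, ContinuousCovariates, combined_scores
from .preprocess import SparsityProfile
from .scores import ScoreConfig

__all__ = [
    "EliminationResult",
    "BiclusterSummary",
    "run_elimination",
    "scramble_bicluster",
    "delineate",
]


@dataclass
class EliminationResult:
    """Orderings and traces of one elimination run.

    ``row_order``/``col_order`` list indices in elimination order (first
    eliminated first; the final survivors are appended in ascending final
    score, so later positions always mean "survived longer").
    ``row_traces``/``col_traces`` hold the mean score of the remaining rows /
    columns at the start of each iteration.
    """

    row_order: np.ndarray
    col_order: np.ndarray
    row_traces: np.ndarray
    col_traces: np.ndarray
    remaining_sizes: list  # per-iteration (rows, cols) at the start of the iteration
    remaining_rows: np.ndarray
    remaining_cols: np.ndarray
    removed_rows_per_iter: list = field(default_factory=list)
    removed_cols_per_iter: list = field(default_factory=list)
    D: np.ndarray | None = None
    X: np.ndarray | None = None
    row_ids: list | None = None
    col_ids: list | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.row_traces)

    def row_ranks(self) -> np.ndarray:
        """rank[i] = elimination position of row i (higher = survived longer)."""
        r = np.empty(len(self.row_order), dtype=np.int64)
        r[self.row_order] = np.arange(len(self.row_order))
        return r

    def col_ranks(self) -> np.ndarray:
        r = np.empty(len(self.col_order), dtype=np.int64)
        r[self.col_order] = np.arange(len(self.col_order))
        return r


@dataclass
class BiclusterSummary:
    """Delineated dominant bicluster: member rows/columns and diagnostics."""

    rows: np.ndarray
    cols: np.ndarray
    peak_iteration: int
    correlations: np.ndarray | None = None
    alignment_auc: float | None = None


def _tie_stable_order(scores, ids):
    """Indices sorted ascending by (score, id) — deterministic under ties."""
    ids = np.asarray(ids)
    return np.lexsort((ids, np.asarray(scores)))


def run_elimination(D, X=None, design: CategoricalDesign | None = None,
                    cov: ContinuousCovariates | None = None,
                    prof: SparsityProfile | None = None,
                    config: ScoreConfig | None = None,
                    row_ids=None, col_ids=None) -> EliminationResult:
    """Iteratively eliminate the lowest-scoring rows and columns.

    Each iteration scores the remaining submatrix with
    :func:`loopbic.corrections.combined_scores` (restricting controls,
    covariates, the sparsity profile and category labels to the surviving
    rows/columns), records the mean row and column score, then removes the
    ``max(1, ceil(gamma * remaining))`` lowest-scoring rows and likewise
    columns (never all of them). Iteration stops when fewer than 2 rows or 2
    columns remain. Ties are broken stably by index, so runs are exactly
    reproducible.
    """
    config = config or ScoreConfig()
    A = check_sign(D)
    m, n = A.shape
    if row_ids is None:
        row_ids = list(getattr(D, "row_ids", [])) or list(range(m))
    if col_ids is None:
        col_ids = list(getattr(D, "col_ids", [])) or list(range(n))
    Xm = check_sign(X) if X is not None else None

    rows = np.arange(m)
    cols = np.arange(n)
    row_order: list[int] = []
    col_order: list[int] = []
    row_traces: list[float] = []
    col_traces: list[float] = []
    removed_r: list[np.ndarray] = []
    removed_c: list[np.ndarray] = []
    remaining_sizes: list[tuple[int, int]] = []

    while rows.size >= 2 and cols.size >= 2:
        remaining_sizes.append((int(rows.size), int(cols.size)))
        sub = A[np.ix_(rows, cols)]
        sub_design = None
        if design is not None:
            labels = design.labels[rows]
            if len(set(labels.tolist())) >= 2:
                sub_design = CategoricalDesign(labels, i_req=min(design.i_req, len(set(labels.tolist()))))
        pair = combined_scores(
            sub,
            X=Xm[:, cols] if Xm is not None else None,
            design=sub_design,
            cov=cov.subset(rows) if cov is not None else None,
            prof=prof.subset(cols) if prof is not None else None,
        )
        zr = np.where(np.isnan(pair.z_row), -np.inf, pair.z_row)
        zc = np.where(np.isnan(pair.z_col), -np.inf, pair.z_col)
        row_traces.append(float(np.mean(pair.z_row[np.isfinite(pair.z_row)]))
                          if np.isfinite(pair.z_row).any() else float("nan"))
        col_traces.append(float(np.mean(pair.z_col[np.isfinite(pair.z_col)]))
                          if np.isfinite(pair.z_col).any() else float("nan"))

        kr = min(max(1, int(np.ceil(config.gamma * rows.size))), rows.size - 1)
        kc = min(max(1, int(np.ceil(config.gamma * cols.size))), cols.size - 1)
        ord_r = _tie_stable_order(zr, rows)
        ord_c = _tie_stable_order(zc, cols)
        drop_r = rows[ord_r[:kr]]
        drop_c = cols[ord_c[:kc]]
        row_order.extend(drop_r.tolist())
        col_order.extend(drop_c.tolist())
        removed_r.append(drop_r)
        removed_c.append(drop_c)
        keep_r = np.ones(rows.size, dtype=bool)
        keep_r[ord_r[:kr]] = False
        keep_c = np.ones(cols.size, dtype=bool)
        keep_c[ord_c[:kc]] = False
        last_zr, last_zc, last_rows, last_cols = zr, zc, rows, cols
        rows = rows[keep_r]
        cols = cols[keep_c]

    # append the survivors, ascending by their final score (stable by index)
    if rows.size:
        surv = {r: s for r, s in zip(last_rows, last_zr)}
        row_order.extend(sorted(rows.tolist(), key=lambda r: (surv[r], r)))
    if cols.size:
        surv = {c: s for c, s in zip(last_cols, last_zc)}
        col_order.extend(sorted(cols.tolist(), key=lambda c: (surv[c], c)))

    return EliminationResult(
        row_order=np.asarray(row_order, dtype=np.int64),
        col_order=np.asarray(col_order, dtype=np.int64),
        row_traces=np.asarray(row_traces),
        col_traces=np.asarray(col_traces),
        remaining_sizes=remaining_sizes,
        remaining_rows=rows,
        remaining_cols=cols,
        removed_rows_per_iter=removed_r,
        removed_cols_per_iter=removed_c,
        D=A, X=Xm, row_ids=list(row_ids), col_ids=list(col_ids),
    )


def scramble_bicluster(D, rows, cols, seed: int = 0) -> np.ndarray:
    """Return a copy of D with the entries of the (rows x cols) block shuffled.

    Destroys the low-rank structure of a found bicluster while preserving the
    block's sign counts; used to search for secondary biclusters.
    """
    A = check_sign(D).copy()
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    rng = derive_rng(seed, 0x5C)
    block = A[np.ix_(rows, cols)].ravel()
    rng.shuffle(block)
    A[np.ix_(rows, cols)] = block.reshape(rows.size, cols.size)
    return A


def _moving_median3(x):
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = np.median(np.stack([x[:-2], x[1:-1], x[2:]]), axis=0)
    return out


def delineate(result: EliminationResult) -> BiclusterSummary:
    """Extract the dominant bicluster from an elimination run.

    The members are the rows and columns still present at the iteration where
    the (median-of-3 smoothed) row trace peaks, restricted to iterations whose
    column trace also exceeds its median (so a row-trace spike with no column
    signal is not selected). The membership is validated by correlating each row of D
    against the leading right singular vector v of the member block:
    ``alignment_auc`` is the probability that a random member row has larger
    |correlation| than a random non-member row (control rows if controls were
    provided, non-member case rows otherwise).
    """
    tr = _moving_median3(result.row_traces)
    if tr.size == 0 or not np.isfinite(tr).any() or np.nanstd(tr) == 0:
        warnings.warn("flat or empty elimination traces; no bicluster delineated", stacklevel=2)
        return BiclusterSummary(rows=np.empty(0, int), cols=np.empty(0, int), peak_iteration=-1)
    tc = _moving_median3(result.col_traces)
    ok = tc > np.nanmedian(tc)
    cand = np.where(ok & np.isfinite(tr), tr, -np.inf)
    peak = int(np.argmax(cand)) if np.isfinite(cand).any() else int(np.nanargmax(tr))

    rows_removed_before = sum(len(r) for r in result.removed_rows_per_iter[:peak])
    cols_removed_before = sum(len(c) for c in result.removed_cols_per_iter[:peak])
    member_rows = np.sort(result.row_order[rows_removed_before:])
    member_cols = np.sort(result.col_order[cols_removed_before:])
    if member_rows.size < 2 or member_cols.size < 2:
        warnings.warn("delineated block too small; no bicluster delineated", stacklevel=2)
        return BiclusterSummary(rows=np.empty(0, int), cols=np.empty(0, int), peak_iteration=peak)

    corrs = None
    auc = None
    if result.D is not None:
        A = result.D
        block = A[np.ix_(member_rows, member_cols)]
        _, _, Vt = np.linalg.svd(block, full_matrices=False)
        v = Vt[0]
        proj = A[:, member_cols] @ v
        sub = A[:, member_cols]
        norms = np.linalg.norm(sub, axis=1) * np.linalg.norm(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            corrs = np.where(norms > 0, proj / norms, 0.0)
        member_mask = np.zeros(A.shape[0], dtype=bool)
        member_mask[member_rows] = True
        if result.X is not None and result.X.shape[0] > 0:
            xproj = result.X[:, member_cols] @ v
            xnorm = np.linalg.norm(result.X[:, member_cols], axis=1) * np.linalg.norm(v)
            with np.errstate(invalid="ignore", divide="ignore"):
                neg = np.abs(np.where(xnorm > 0, xproj / xnorm, 0.0))
            pos = np.abs(corrs[member_mask])
        else:
            pos = np.abs(corrs[member_mask])
            neg = np.abs(corrs[~member_mask])
        if pos.size and neg.size:
            from ._util import rank_auc
            auc = rank_auc(pos, neg)

    return BiclusterSummary(rows=member_rows, cols=member_cols, peak_iteration=peak,
                            correlations=corrs, alignment_auc=auc)
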