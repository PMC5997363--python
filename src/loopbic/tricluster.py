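"""Loop-counting on 3-D data cubes: tri-scores and three-axis elimination.

A cube loop fixes one axis index and takes a 2x2 pattern over the other two
axes; there are three loop categories (iso-layer, iso-column, iso-row). Each
axis is scored by adding the normalized sums of the two loop categories that
pair indices on that axis. Because every entry is +/-1, each category's sum
collapses to a squared Gram tensor minus its diagonal count, so no loop is
ever enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scores import ScoreConfig

__all__ = ["DataCube", "TriScores", "TriEliminationResult", "tri_scores", "tri_eliminate"]


@dataclass
class DataCube:
    """A +/-1 array of shape M x N x P (patients x measurements x layers)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("DataCube requires a 3-D array")
        if not np.all(np.abs(v.astype(np.float64)) == 1.0):
            raise ValueError("DataCube entries must be exactly -1 or +1")
        self.values = v.astype(np.int8)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class TriScores:
    z_row: np.ndarray
    z_col: np.ndarray
    z_lyr: np.ndarray


def _check_cube(cube) -> np.ndarray:
    v = np.asarray(getattr(cube, "values", cube), dtype=np.float64)
    if v.ndim != 3:
        raise ValueError("expected a 3-D array")
    if not np.all(np.abs(v) == 1.0):
        raise ValueError("cube entries must be exactly -1 or +1; binarize first")
    return v


def _pair_sum(C, spec, contracted, per_axis_count):
    """Normalized loop sum from one Gram tensor.

    ``spec`` is the einsum pairing (e.g. "jkl,Jkl->jJl"); the loop sum for the
    scored index is sum over partner != self of (gram^2 - contracted), summed
    over the free third axis, divided by the total number of loop terms.
    Returns zeros when the sum is empty (fewer than 2 partners or no loops).
    """
    if per_axis_count <= 0:
        return None
    G = np.einsum(spec, C, C)
    Q = G * G - contracted
    s = Q.sum(axis=(1, 2)) - np.einsum("iik->i", Q)
    return s / per_axis_count


def tri_scores(cube) -> TriScores:
    """Row, column, and layer scores of a sign cube.

    z_row_j adds the normalized iso-layer sum (row pairs j' != j, column pairs
    k' != k, any layer) and the normalized iso-column sum (row pairs, layer
    pairs, any column); z_col and z_lyr are the analogous combinations of the
    two categories pairing their axis. Each constituent sum is divided by its
    own number of summands (scores of a coherent block approach 2 = 1 + 1);
    an empty constituent (a dimension of size < 2) contributes 0.
    """
    C = _check_cube(cube)
    m, n, p = C.shape

    def term(spec, contracted, count, size):
        out = _pair_sum(C, spec, contracted, count)
        return out if out is not None else np.zeros(size)

    # rows: iso-layer (pairs j,J within each layer) + iso-column (pairs j,J within each column)
    z_row = (term("jkl,Jkl->jJl", n, (m - 1) * n * (n - 1) * p, m)
             + term("jkl,Jkl->jJk", p, (m - 1) * p * (p - 1) * n, m))
    # columns: iso-layer (pairs k,K within each layer) + iso-row (pairs k,K within each row)
    z_col = (term("jkl,jKl->kKl", m, m * (m - 1) * (n - 1) * p, n)
             + term("jkl,jKl->kKj", p, m * (n - 1) * p * (p - 1), n))
    # layers: iso-column (pairs l,L within each column) + iso-row (pairs l,L within each row)
    z_lyr = (term("jkl,jkL->lLk", m, m * (m - 1) * (p - 1) * n, p)
             + term("jkl,jkL->lLj", n, m * n * (n - 1) * (p - 1), p))
    return TriScores(z_row=z_row, z_col=z_col, z_lyr=z_lyr)


@dataclass
class TriEliminationResult:
    """Elimination orderings and traces over the three cube axes."""

    row_order: np.ndarray
    col_order: np.ndarray
    lyr_order: np.ndarray
    row_traces: np.ndarray
    col_traces: np.ndarray
    lyr_traces: np.ndarray
    remaining_sizes: list = field(default_factory=list)

    def ranks(self, axis: int) -> np.ndarray:
        order = (self.row_order, self.col_order, self.lyr_order)[axis]
        r = np.empty(order.size, dtype=np.int64)
        r[order] = np.arange(order.size)
        return r


def tri_eliminate(cube, config: ScoreConfig | None = None) -> TriEliminationResult:
    """Iteratively remove the lowest-scoring rows, columns, and layers.

    Each iteration scores the remaining sub-cube with :func:`tri_scores`,
    records the mean score per axis, and removes the ``max(1, ceil(gamma *
    remaining))`` lowest-scoring indices on each axis (never all of them).
    Stops when any axis has fewer than 2 surviving indices; survivors are
    appended in ascending final score. Ties break stably by index.
    """
    config = config or ScoreConfig()
    C = _check_cube(cube)
    idx = [np.arange(s) for s in C.shape]
    orders: list[list[int]] = [[], [], []]
    traces: list[list[float]] = [[], [], []]
    remaining_sizes: list[tuple[int, int, int]] = []

    while all(ax.size >= 2 for ax in idx):
        remaining_sizes.append(tuple(int(ax.size) for ax in idx))
        sub = C[np.ix_(*idx)]
        zs = tri_scores(sub)
        last = []
        for a, z in enumerate((zs.z_row, zs.z_col, zs.z_lyr)):
            traces[a].append(float(np.mean(z)))
            k = min(max(1, int(np.ceil(config.gamma * idx[a].size))), idx[a].size - 1)
            order = np.lexsort((idx[a], z))
            drop = idx[a][order[:k]]
            orders[a].extend(drop.tolist())
            keep = np.ones(idx[a].size, dtype=bool)
            keep[order[:k]] = False
            last.append((idx[a], z))
            idx[a] = idx[a][keep]

    for a in range(3):
        if idx[a].size:
            ids, z = last[a]
            surv = {i: s for i, s in zip(ids, z)}
            orders[a].extend(sorted(idx[a].tolist(), key=lambda i: (surv[i], i)))

    return TriEliminationResult(
        row_order=np.asarray(orders[0], dtype=np.int64),
        col_order=np.asarray(orders[1], dtype=np.int64),
        lyr_order=np.asarray(orders[2], dtype=np.int64),
        row_traces=np.asarray(traces[0]),
        col_traces=np.asarray(traces[1]),
        lyr_traces=np.asarray(traces[2]),
        remaining_sizes=remaining_sizes,
    )
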