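"""Planted-bicluster simulations, recovery AUC and phase diagrams.

The benchmark plants an m x m block of controlled rank-structure (l leading
unit singular values, the remaining m - l set to epsilon) inside an M x M
matrix of independent random signs, then asks how well an ordering recovers
the planted rows and columns. Success is summarized by the AUC A: the
probability that a random non-member is eliminated before a random member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import derive_rng, derive_seed, rank_auc
from .elimination import EliminationResult, run_elimination
from .scores import ScoreConfig, d_scores, spectral_scores

__all__ = [
    "PlantedProblem",
    "make_planted",
    "estimate_g",
    "evaluate_auc",
    "detection_boundary",
    "one_shot_order",
    "phase_diagram",
]


@dataclass
class PlantedProblem:
    """An ambient sign matrix with a planted low-rank sign block."""

    D: np.ndarray
    rows: np.ndarray          # planted row indices (length m)
    cols: np.ndarray          # planted column indices (length m)
    m: int
    l: int
    epsilon: float
    seed: int


def _planted_block(m: int, l: int, epsilon: float, rng) -> np.ndarray:
    """m x m sign block whose pre-binarization singular values are
    (1, ..., 1, eps, ..., eps) with l leading ones."""
    if not (1 <= l <= m):
        raise ValueError("need 1 <= l <= m")
    G = rng.standard_normal((m, m))
    U, _, Vt = np.linalg.svd(G)
    s = np.full(m, float(epsilon))
    s[:l] = 1.0
    B = (U * s) @ Vt
    signs = np.where(B >= 0, 1.0, -1.0)
    return signs


def make_planted(M: int, m: int, l: int = 1, epsilon: float = 0.0,
                 seed: int = 0, ambient: str = "rademacher") -> PlantedProblem:
    """Plant an m x m rank-controlled sign block in an M x M random matrix.

    The ambient entries are independent fair signs; the planted block is a
    Gaussian matrix whose singular values are reset to l ones followed by
    epsilons, binarized by sign. Row and column positions are drawn without
    replacement. epsilon = 0 with l = 1 plants an exactly rank-1 block.
    """
    if ambient != "rademacher":
        raise ValueError(f"unknown ambient {ambient!r}")
    if m > M:
        raise ValueError("planted block cannot exceed the matrix")
    rng = derive_rng(seed, 0x9A)
    D = rng.choice(np.array([-1.0, 1.0]), size=(M, M))
    rows = np.sort(rng.choice(M, size=m, replace=False))
    cols = np.sort(rng.choice(M, size=m, replace=False))
    D[np.ix_(rows, cols)] = _planted_block(m, l, epsilon, rng)
    return PlantedProblem(D=D, rows=rows, cols=cols, m=m, l=l,
                          epsilon=float(epsilon), seed=int(seed))


def estimate_g(l: int, epsilon: float, m: int, n_mc: int = 20_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of g: the probability that a random loop of the
    planted block is rank-1 (product of its four entries +1).

    g = 1 for an exactly rank-1 block; g -> 1/2 as the block loses structure.
    Sampled by drawing blocks and random (j != j', k != k') quadruples.
    """
    rng = derive_rng(seed, 0x6E)
    n_blocks = max(1, n_mc // max(1, m))
    per_block = max(1, n_mc // n_blocks)
    hits = 0
    total = 0
    for _ in range(n_blocks):
        B = _planted_block(m, l, epsilon, rng)
        j = rng.integers(0, m, size=per_block)
        jp = (j + 1 + rng.integers(0, m - 1, size=per_block)) % m
        k = rng.integers(0, m, size=per_block)
        kp = (k + 1 + rng.integers(0, m - 1, size=per_block)) % m
        prod = B[j, k] * B[jp, k] * B[jp, kp] * B[j, kp]
        hits += int((prod > 0).sum())
        total += per_block
    return hits / total


def detection_boundary(l: int, epsilon: float, m: int, M: int,
                       p: float = 1.0, s: float = 1.5, c: float = 2.0,
                       n_mc: int = 20_000, seed: int = 0) -> bool:
    """Predict whether a planted block is detectable: m^3 (2g - 1)^p >= c M^s.

    g is the rank-1 loop fraction of the planted block (see
    :func:`estimate_g`). With the defaults, an exactly rank-1 block (g = 1)
    is predicted detectable when m >= (c)^(1/3) M^(1/2) — i.e. when
    log_M(m) clears 1/2 for large M.
    """
    g = estimate_g(l, epsilon, m, n_mc=n_mc, seed=seed)
    return bool(m**3 * max(0.0, 2.0 * g - 1.0) ** p >= c * M**s)


def evaluate_auc(result_or_row_ranks, truth: PlantedProblem,
                 col_ranks=None) -> dict:
    """Recovery AUC of an ordering against the planted truth.

    A_R = P(random non-member row eliminated before a random member row),
    computed exactly from rank positions; A_C likewise for columns;
    A = (A_R + A_C) / 2. Accepts an :class:`EliminationResult` or raw rank
    arrays (higher rank = survived longer).
    """
    if isinstance(result_or_row_ranks, EliminationResult):
        rr = result_or_row_ranks.row_ranks()
        cr = result_or_row_ranks.col_ranks()
    else:
        rr = np.asarray(result_or_row_ranks)
        cr = np.asarray(col_ranks)
    M = rr.size
    mem_r = np.zeros(M, dtype=bool)
    mem_r[truth.rows] = True
    mem_c = np.zeros(cr.size, dtype=bool)
    mem_c[truth.cols] = True
    a_r = rank_auc(rr[mem_r], rr[~mem_r])
    a_c = rank_auc(cr[mem_c], cr[~mem_c])
    return {"A_row": a_r, "A_col": a_c, "A": 0.5 * (a_r + a_c)}


def one_shot_order(D, method: str = "spectral", d: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Row/column ranks from a single scoring pass (no elimination).

    ``method``: "spectral" (entrywise-squared leading singular vectors) or
    "d" (diag((D D^T)^(d+1)), requires ``d``). Higher rank = higher score.
    """
    if method == "spectral":
        pair = spectral_scores(D)
    elif method == "d":
        if d is None:
            raise ValueError("method='d' requires d")
        pair = d_scores(D, d, rescale=True)
    else:
        raise ValueError(f"unknown method {method!r}")

    def ranks(z):
        order = np.lexsort((np.arange(z.size), z))
        r = np.empty(z.size, dtype=np.int64)
        r[order] = np.arange(z.size)
        return r

    return ranks(pair.z_row), ranks(pair.z_col)


def _trial_auc(M, m, l, epsilon, method, config, trial_seed):
    prob = make_planted(M, m, l=l, epsilon=epsilon, seed=trial_seed)
    if method == "loop":
        res = run_elimination(prob.D, config=config)
        return evaluate_auc(res, prob)["A"]
    rr, cr = one_shot_order(prob.D, method="spectral")
    return evaluate_auc(rr, prob, col_ranks=cr)["A"]


def phase_diagram(M: int, m_values, epsilon_values, l: int = 1,
                  methods=("loop",), n_trials: int = 4, seed: int = 0,
                  config: ScoreConfig | None = None) -> pd.DataFrame:
    """Mean recovery AUC over a grid of block sizes and epsilon values.

    Returns one row per (m, epsilon, method) cell with columns
    ``m``, ``epsilon``, ``epsilon_m`` (= epsilon * m, log10 of which is the
    natural x-axis), ``logM_m`` (= log m / log M), ``method``, ``mean_A`` and
    ``n_trials``. Per-trial seeds are derived from (seed, cell, trial), so
    cells are independent of iteration order.
    """
    config = config or ScoreConfig()
    rows = []
    for ci, m in enumerate(m_values):
        for cj, eps in enumerate(epsilon_values):
            for method in methods:
                aucs = [
                    _trial_auc(M, int(m), l, float(eps), method, config,
                               derive_seed(seed, ci, cj, t))
                    for t in range(n_trials)
                ]
                rows.append({
                    "m": int(m),
                    "epsilon": float(eps),
                    "epsilon_m": float(eps) * int(m),
                    "logM_m": float(np.log(m) / np.log(M)),
                    "method": method,
                    "mean_A": float(np.mean(aucs)),
                    "n_trials": n_trials,
                })
    return pd.DataFrame(rows)
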