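"""Shared helpers: RNG derivation, sign-matrix validation, rank AUC."""

from __future__ import annotations

import numpy as np

__all__ = ["derive_rng", "derive_seed", "check_sign", "rank_auc"]


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child generator for (seed, keys).

    Every stochastic routine in the package draws its generator through this
    function so that a single master seed reproduces a whole run, and parallel
    or per-cell substreams (keyed by e.g. grid coordinates, trial index) stay
    independent of execution order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *[int(k) for k in keys]]))


def derive_seed(seed: int, *keys: int) -> int:
    """A child integer seed below 2**31, for APIs that take a seed."""
    return int(derive_rng(seed, *keys).integers(0, 2**31))


def check_sign(D) -> np.ndarray:
    """Validate a +/-1 matrix and return it as a float64 array."""
    A = np.asarray(getattr(D, "values", D), dtype=np.float64)
    if A.ndim < 2:
        raise ValueError(f"expected a 2-D (or higher) array, got shape {A.shape}")
    if not np.all(np.abs(A) == 1.0):
        raise ValueError("matrix entries must be exactly -1 or +1; binarize first")
    return A


def rank_auc(scores_pos, scores_neg) -> float:
    """Exact AUC: P(random positive > random negative), ties counted 1/2.

    Computed from ranks (Mann-Whitney), no trapezoids, no sampling.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    allv = np.concatenate([pos, neg])
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(allv.size, dtype=float)
    # midranks for ties
    sv = allv[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
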