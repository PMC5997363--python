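"""Normalization, binarization and per-column sparsity estimation.

The scoring machinery operates on sign matrices: every entry is +1 or -1.
Expression data is median-centered per gene and then binarized by sign;
genotype dosages (0/1/2 minor-allele counts) are binarized by a presence
threshold. Columns with unbalanced signs (low minor-allele frequency) get a
:class:`SparsityProfile` whose centering vector ``alpha`` and diagonal weights
``delta`` feed the sparsity-corrected scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawMatrix",
    "SignMatrix",
    "SparsityProfile",
    "median_center",
    "binarize",
    "binarize_genotypes",
    "estimate_sparsity",
]


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


@dataclass
class RawMatrix:
    """Real-valued patients x measurements matrix with identifiers."""

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("RawMatrix requires a 2-D array")
        if self.values.size == 0:
            raise ValueError("empty matrix")
        m, n = self.values.shape
        if not self.row_ids:
            self.row_ids = _default_ids("p", m)
        if not self.col_ids:
            self.col_ids = _default_ids("g", n)
        if len(self.row_ids) != m or len(self.col_ids) != n:
            raise ValueError("id lengths do not match matrix shape")
        if np.isnan(self.values).any():
            raise ValueError(
                "matrix contains missing values; impute or drop them first "
                "(see median_center(..., impute_missing=True))"
            )

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SignMatrix:
    """A matrix whose entries are exactly -1 or +1."""

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.all(np.abs(v.astype(np.float64)) == 1.0):
            raise ValueError("SignMatrix entries must be exactly -1 or +1")
        self.values = v.astype(np.int8)
        m, n = self.values.shape
        if not self.row_ids:
            self.row_ids = _default_ids("p", m)
        if not self.col_ids:
            self.col_ids = _default_ids("g", n)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class SparsityProfile:
    """Per-column fraction of +1 entries and derived centering/weights.

    ``p`` is clamped away from {0, 1} so the loop weight ``delta`` (with
    delta_k = 1 / (4 p_k q_k)) stays finite even for constant columns.
    """

    p: np.ndarray
    clamp: float

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if not (0.0 < self.clamp < 0.5):
            raise ValueError("clamp must lie in (0, 0.5)")
        self.p = np.clip(self.p, self.clamp, 1.0 - self.clamp)

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def alpha(self) -> np.ndarray:
        """Per-column mean of a +/-1 column with +1-fraction p: 2p - 1."""
        return 2.0 * self.p - 1.0

    @property
    def delta(self) -> np.ndarray:
        """Diagonal loop weights, reciprocal of the column variance 4pq."""
        return 1.0 / (4.0 * self.p * self.q)

    def subset(self, cols) -> "SparsityProfile":
        return SparsityProfile(self.p[np.asarray(cols)], self.clamp)


def median_center(raw: RawMatrix | np.ndarray, impute_missing: bool = False) -> RawMatrix:
    """Subtract each column's median (gene normalized to median 0).

    With ``impute_missing`` missing entries are first replaced by the column
    median of the observed values; by default missing data is rejected.
    """
    if isinstance(raw, RawMatrix):
        vals, rids, cids = raw.values.copy(), raw.row_ids, raw.col_ids
    else:
        vals = np.array(raw, dtype=np.float64)
        if vals.size == 0:
            raise ValueError("empty matrix")
        rids, cids = [], []
    if np.isnan(vals).any():
        if not impute_missing:
            raise ValueError("matrix contains missing values")
        med = np.nanmedian(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = np.take(med, idx[1])
    vals = vals - np.median(vals, axis=0, keepdims=True)
    return RawMatrix(vals, list(rids), list(cids))


def binarize(raw, zero_policy: str = "to_minus_one", seed: int = 0) -> SignMatrix:
    """Map each entry to its sign; zeros go to -1 by default (2*(D>0) - 1).

    ``zero_policy`` may be ``to_minus_one``, ``to_plus_one`` or ``random``
    (fair coin per zero entry, seeded). Idempotent on sign matrices.
    """
    if isinstance(raw, SignMatrix):
        vals = raw.values.astype(np.float64)
        rids, cids = raw.row_ids, raw.col_ids
    elif isinstance(raw, RawMatrix):
        vals, rids, cids = raw.values, raw.row_ids, raw.col_ids
    else:
        vals = np.asarray(raw, dtype=np.float64)
        rids, cids = [], []
    out = np.where(vals > 0, 1.0, -1.0)
    zeros = vals == 0
    if zeros.any():
        if zero_policy == "to_minus_one":
            pass  # sign already -1
        elif zero_policy == "to_plus_one":
            out[zeros] = 1.0
        elif zero_policy == "random":
            rng = np.random.default_rng(seed)
            out[zeros] = rng.choice([-1.0, 1.0], size=int(zeros.sum()))
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return SignMatrix(out.astype(np.int8), list(rids), list(cids))


def binarize_genotypes(dosages, threshold: float = 0.5) -> SignMatrix:
    """Binarize 0/1/2 minor-allele dosages: presence (dosage > threshold) -> +1.

    The mapping of genotypes to signs is a configuration choice; the default
    marks any copy of the minor allele as +1, so the +1-fraction of a column
    tracks its minor-allele frequency.
    """
    vals = np.asarray(getattr(dosages, "values", dosages), dtype=np.float64)
    return binarize(np.where(vals > threshold, 1.0, -1.0))


def estimate_sparsity(D: SignMatrix | np.ndarray, clamp: float | None = None) -> SparsityProfile:
    """Per-column +1 fraction of a sign matrix, clamped to [clamp, 1-clamp].

    Default clamp is 1/(2M): a constant column is treated as if a fraction of
    half an entry disagreed, keeping the delta weight finite.
    """
    vals = np.asarray(getattr(D, "values", D), dtype=np.float64)
    m = vals.shape[0]
    if clamp is None:
        clamp = 1.0 / (2.0 * m)
    p = (vals > 0).mean(axis=0)
    return SparsityProfile(p, clamp=float(clamp))
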