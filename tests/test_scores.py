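import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopbic.scores import (
    ScoreConfig,
    d_scores,
    loop_scores,
    loop_scores_bruteforce,
    spectral_scores,
)


def _rad(rng, m, n):
    return rng.choice(np.array([-1.0, 1.0]), size=(m, n))


def test_loop_scores_all_ones():
    # every loop of an all-ones matrix is rank-1: raw score = diag((DD^T)^2)
    D = np.ones((3, 4))
    p = loop_scores(D)
    assert np.array_equal(p.z_row, np.full(3, (3 * 4) ** 2 // 3))  # (DD^T)=4*ones -> diag=48
    assert (p.z_row == 48).all()
    assert (p.z_col == 36).all()


def test_loop_scores_normalized_rank1_is_one():
    rng = np.random.default_rng(1)
    u = rng.choice([-1.0, 1.0], size=8)
    v = rng.choice([-1.0, 1.0], size=9)
    D = np.outer(u, v)
    p = loop_scores(D, normalized=True)
    assert np.allclose(p.z_row, 1.0)
    assert np.allclose(p.z_col, 1.0)


def test_loop_scores_normalized_bounds(rng):
    for _ in range(20):
        D = _rad(rng, rng.integers(2, 10), rng.integers(2, 10))
        p = loop_scores(D, normalized=True)
        assert np.all(p.z_row <= 1.0 + 1e-12) and np.all(p.z_row >= -1.0 - 1e-12)
        assert np.all(p.z_col <= 1.0 + 1e-12) and np.all(p.z_col >= -1.0 - 1e-12)


def test_loop_scores_match_bruteforce(rng):
    for _ in range(10):
        D = _rad(rng, rng.integers(2, 8), rng.integers(2, 9))
        fast = loop_scores(D)
        slow = loop_scores_bruteforce(D)
        assert np.array_equal(fast.z_row, slow.z_row.astype(np.int64))
        assert np.array_equal(fast.z_col, slow.z_col.astype(np.int64))


def test_loop_scores_rejects_non_sign():
    with pytest.raises(ValueError):
        loop_scores(np.array([[1.0, 0.5], [1.0, -1.0]]))


def test_d_scores_d1_equals_loop_scores(rng):
    D = _rad(rng, 6, 7)
    assert np.array_equal(d_scores(D, 1).z_row, loop_scores(D).z_row)
    assert np.array_equal(d_scores(D, 1).z_col, loop_scores(D).z_col)
    with pytest.raises(ValueError):
        d_scores(D, 0)


def test_d_scores_converge_to_spectral(rng):
    # ranking by large-d scores approaches the spectral ranking
    u = np.ones(12)
    v = np.ones(10)
    D = _rad(rng, 12, 10)
    D[:6, :5] = np.outer(u[:6], v[:5])
    big = d_scores(D, 12, rescale=True)
    spec = spectral_scores(D)
    assert np.array_equal(np.sort(np.argsort(big.z_row)[-6:]), np.sort(np.argsort(spec.z_row)[-6:]))


def test_spectral_scores_sum_to_one(rng):
    D = _rad(rng, 9, 11)
    p = spectral_scores(D)
    assert np.isclose(p.z_row.sum(), 1.0)
    assert np.isclose(p.z_col.sum(), 1.0)


def test_spectral_tie_break_deterministic():
    # identity-like matrix has fully degenerate spectrum; projector diagonal is uniform
    D = np.ones((4, 4))
    D[np.arange(4), np.arange(4)] = -1.0  # symmetric, two tied leading values
    p1 = spectral_scores(D)
    p2 = spectral_scores(D)
    assert np.array_equal(p1.z_row, p2.z_row)
    assert np.isclose(p1.z_row.sum(), 1.0)
    assert p1.extras["n_tied"] >= 2


def test_score_config_validation():
    with pytest.raises(ValueError):
        ScoreConfig(gamma=0.0)
    with pytest.raises(ValueError):
        ScoreConfig(d=0)
    assert ScoreConfig().gamma == 0.05


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(2, 7), st.integers(2, 7), st.integers(0, 2**31 - 1))
def test_loop_score_row_col_totals_agree(m, n, seed):
    # the total over rows and the total over columns both count all loops
    rng = np.random.default_rng(seed)
    D = _rad(rng, m, n)
    p = loop_scores(D)
    assert p.z_row.sum() == p.z_col.sum()
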