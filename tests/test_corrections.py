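import numpy as np
import pytest

from loopbic import bruteforce as bf
from loopbic.corrections import (
    CategoricalDesign,
    ContinuousCovariates,
    ControlSplit,
    categorical_scores,
    combined_scores,
    continuous_scores,
    control_scores,
    kappa_squared,
    sparsity_scores,
)
from loopbic.preprocess import SparsityProfile
from loopbic.scores import loop_scores

ONES22 = np.ones((2, 2))
X_ANTI = np.array([[1.0, -1.0], [-1.0, 1.0]])


def _rad(rng, m, n):
    return rng.choice(np.array([-1.0, 1.0]), size=(m, n))


# ------------------------------------------------------------------ controls


def test_control_worked_examples():
    p = control_scores(D=ONES22, X=ONES22)
    assert np.allclose(p.z_row, 0.0) and np.allclose(p.z_col, 0.0)
    p = control_scores(D=ONES22, X=X_ANTI)
    assert np.allclose(p.z_row, 2.0)


def test_control_random_x_mean_one():
    # D all-ones, X iid: case term is 1, cross term averages to 0
    rng = np.random.default_rng(4)
    means = [control_scores(D=ONES22, X=_rad(rng, 2, 2)).z_row.mean() for _ in range(2000)]
    assert abs(np.mean(means) - 1.0) < 3 * np.std(means) / np.sqrt(len(means))


def test_control_bound_and_oracle(rng):
    for _ in range(15):
        D = _rad(rng, rng.integers(2, 8), rng.integers(2, 9))
        X = _rad(rng, rng.integers(1, 7), D.shape[1])
        p = control_scores(D=D, X=X)
        assert np.all(np.abs(p.z_row) <= 2 + 1e-12)
        assert np.all(np.abs(p.z_col) <= 2 + 1e-12)
        zr, zc = bf.oracle_control_scores(D, X)
        assert np.allclose(p.z_row, zr, atol=1e-12)
        assert np.allclose(p.z_col, zc, atol=1e-12)


def test_control_split_validation():
    with pytest.raises(ValueError):
        ControlSplit(np.ones((1, 3)), np.ones((2, 3)))
    with pytest.raises(ValueError):
        ControlSplit(np.ones((2, 3)), np.ones((2, 4)))


# --------------------------------------------------------------- categorical


def test_categorical_worked_examples():
    p = categorical_scores([ONES22, ONES22])
    assert np.allclose(p.z_row, 6.0)
    p = categorical_scores([ONES22, X_ANTI])
    assert np.allclose(p.z_row[:2], -6.0)


def test_categorical_oracle(rng):
    for _ in range(10):
        n = rng.integers(2, 9)
        D1 = _rad(rng, rng.integers(2, 7), n)
        D2 = _rad(rng, rng.integers(2, 7), n)
        p = categorical_scores([D1, D2])
        assert np.allclose(p.z_row, bf.oracle_categorical_row(D1, D2), atol=1e-9)
        assert np.allclose(p.z_col, bf.oracle_categorical_col(D1, D2), atol=1e-9)


def test_categorical_requires_two_patients():
    with pytest.raises(ValueError):
        categorical_scores([np.ones((1, 3)), np.ones((2, 3))])


def test_categorical_three_blocks_runs(rng):
    blocks = [_rad(rng, 3, 5) for _ in range(3)]
    p = categorical_scores(blocks, i_req=2)
    assert p.z_row.shape == (9,)
    assert p.z_col.shape == (5,)


def test_categorical_design_validation():
    d = CategoricalDesign(np.array(["a", "b", "a"]))
    assert set(d.groups()) == {"a", "b"}
    with pytest.raises(ValueError):
        CategoricalDesign(np.array(["a", "a"]), i_req=3)


# ---------------------------------------------------------------- continuous


def test_kappa_squared_values():
    k2 = kappa_squared(2, n_mc=100_000, seed=0)
    assert abs(k2 - 1.0 / 3.0) < 0.005
    assert kappa_squared(1, n_mc=10_000, seed=0) == pytest.approx(1.0, abs=1e-12)
    # stability across seeds
    assert abs(kappa_squared(2, n_mc=100_000, seed=1) - k2) < 0.01
    # sphere ensemble option
    assert abs(kappa_squared(2, n_mc=100_000, seed=0, ensemble="sphere") - 0.375) < 0.01
    with pytest.raises(ValueError):
        kappa_squared(0)
    with pytest.warns(UserWarning):
        kappa_squared(2, n_mc=100)


def test_continuous_worked_examples():
    D = np.ones((4, 3))
    concentrated = ContinuousCovariates(np.tile([1.0, 0.0], (4, 1)), kappa2=0.34)
    p = continuous_scores(D, concentrated)
    assert np.allclose(p.extras["z_row_sq"], 1 - 1 / (2 * 0.34))  # approx -0.4706
    balanced = ContinuousCovariates(
        np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]]), kappa2=0.34)
    p = continuous_scores(D, balanced)
    assert np.allclose(p.extras["z_row_sq"], 1.0)
    zero = ContinuousCovariates(np.zeros((4, 2)), kappa2=0.34)
    p = continuous_scores(D, zero)
    assert np.allclose(p.extras["z_row_sq"], 1.0)  # floor(base)^2 with no covariate term


def test_continuous_oracle(rng):
    for _ in range(10):
        D = _rad(rng, rng.integers(3, 8), rng.integers(3, 9))
        cov = ContinuousCovariates(rng.standard_normal((D.shape[0], rng.integers(1, 4))),
                                   kappa2=0.34)
        p = continuous_scores(D, cov)
        ozsq, ozc = bf.oracle_continuous_scores(D, cov.T, 0.34)
        assert np.allclose(p.extras["z_row_sq"], ozsq, atol=1e-12)
        assert np.allclose(p.z_col, ozc, atol=1e-12)


def test_continuous_unit_normalization():
    cov = ContinuousCovariates(np.array([[3.0, 4.0], [0.0, 0.0]]))
    assert np.allclose(cov.T[0], [0.6, 0.8])
    assert np.allclose(cov.T[1], [0.0, 0.0])


# ------------------------------------------------------------------ sparsity


def test_sparsity_reduces_at_half():
    rng = np.random.default_rng(2)
    D = _rad(rng, 7, 9)
    prof = SparsityProfile(np.full(9, 0.5), clamp=0.01)
    p = sparsity_scores(D, prof)
    u = loop_scores(D, normalized=True)
    assert np.allclose(p.z_row, u.z_row)
    assert np.allclose(p.z_col, u.z_col)


def test_sparsity_oracle(rng):
    for _ in range(10):
        D = _rad(rng, rng.integers(3, 8), rng.integers(3, 9))
        prof = SparsityProfile(rng.uniform(0.1, 0.9, size=D.shape[1]), clamp=0.01)
        p = sparsity_scores(D, prof)
        zr, zc = bf.oracle_sparsity_scores(D, prof)
        assert np.allclose(p.z_row, zr, rtol=1e-10, atol=1e-12)
        assert np.allclose(p.z_col, zc, rtol=1e-10, atol=1e-12)


def test_sparsity_constant_column_contributes_nothing():
    rng = np.random.default_rng(3)
    D = _rad(rng, 20, 6)
    D[:, 0] = 1.0
    from loopbic.preprocess import estimate_sparsity
    prof = estimate_sparsity(D)
    p = sparsity_scores(D, prof)
    # centered entries of the constant column are ~0; its column score is tiny
    assert abs(p.z_col[0]) < 0.05 * np.abs(p.z_col[1:]).max()


# ------------------------------------------------------------------ combined


def test_combined_identity_composition(rng):
    D = _rad(rng, 8, 10)
    p = combined_scores(D)
    u = loop_scores(D, normalized=True)
    assert np.allclose(p.z_row, u.z_row)
    assert np.allclose(p.z_col, u.z_col)


def test_combined_sparsity_only_matches_sparsity(rng):
    D = _rad(rng, 8, 10)
    prof = SparsityProfile(rng.uniform(0.2, 0.8, size=10), clamp=0.01)
    p = combined_scores(D, prof=prof)
    s = sparsity_scores(D, prof)
    assert np.allclose(p.z_row, s.z_row)
    assert np.allclose(p.z_col, s.z_col)


def test_combined_control_only_matches_control(rng):
    D = _rad(rng, 8, 10)
    X = _rad(rng, 5, 10)
    p = combined_scores(D, X=X)
    c = control_scores(D=D, X=X)
    assert np.allclose(p.z_row, c.z_row)
    assert np.allclose(p.z_col, c.z_col)


def test_combined_end_to_end_recovery(rng):
    # case-specific, covariate-balanced, MAF-heterogeneous planted bicluster
    from loopbic._util import rank_auc
    m, n, mb, nb = 60, 120, 18, 30
    maf = rng.uniform(0.2, 0.5, size=n)
    D = np.where(rng.uniform(size=(m, n)) < maf, 1.0, -1.0)
    X = np.where(rng.uniform(size=(40, n)) < maf, 1.0, -1.0)
    u = rng.choice([-1.0, 1.0], size=mb)
    v = rng.choice([-1.0, 1.0], size=nb)
    D[np.ix_(np.arange(mb), np.arange(nb))] = np.outer(u, v)
    labels = np.array((["a", "b"] * m)[:m])
    cov = ContinuousCovariates(rng.standard_normal((m, 2)), kappa2=1 / 3)
    prof = SparsityProfile(maf, clamp=0.01)
    p = combined_scores(D, X=X, design=CategoricalDesign(labels), cov=cov, prof=prof)
    mem_r = np.zeros(m, bool)
    mem_r[:mb] = True
    mem_c = np.zeros(n, bool)
    mem_c[:nb] = True
    assert rank_auc(p.z_row[mem_r], p.z_row[~mem_r]) >= 0.9
    assert rank_auc(p.z_col[mem_c], p.z_col[~mem_c]) >= 0.9
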