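from fractions import Fraction

import numpy as np
import pytest

from loopbic._util import derive_seed
from loopbic.planted import (
    detection_boundary,
    estimate_g,
    evaluate_auc,
    make_planted,
    one_shot_order,
    phase_diagram,
)


def test_planted_block_spectrum():
    rng = np.random.default_rng(0)
    # construction check on the pre-binarization spectrum
    m, l, eps = 12, 3, 0.25
    G = rng.standard_normal((m, m))
    U, _, Vt = np.linalg.svd(G)
    s = np.full(m, eps)
    s[:l] = 1.0
    B = (U * s) @ Vt
    sv = np.linalg.svd(B, compute_uv=False)
    assert np.allclose(sv[:l], sv[0], atol=1e-12)
    assert np.isclose(sv[l] / sv[0], eps, atol=1e-12)


def test_make_planted_masks_and_rank1_loops():
    prob = make_planted(50, 10, l=1, epsilon=0.0, seed=1)
    assert prob.rows.size == 10 and prob.cols.size == 10
    B = prob.D[np.ix_(prob.rows, prob.cols)]
    # every non-degenerate loop of a rank-1 sign block has product +1
    for j in range(10):
        for J in range(j + 1, 10):
            prod = B[j] * B[J]
            outer = prod[:, None] * prod[None, :]
            assert np.all(outer == 1)


def test_make_planted_validation():
    with pytest.raises(ValueError):
        make_planted(10, 20, seed=0)
    with pytest.raises(ValueError):
        make_planted(10, 5, l=0, seed=0)


def test_estimate_g_extremes_and_monotone():
    assert estimate_g(1, 0.0, 20, n_mc=2000, seed=0) == 1.0
    g_noise = estimate_g(1, 1.0, 20, n_mc=20000, seed=0)
    assert abs(g_noise - 0.5) < 0.02
    gs = [estimate_g(2, e, 20, n_mc=20000, seed=1) for e in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert all(a >= b - 0.02 for a, b in zip(gs, gs[1:]))


def test_estimate_g_seed_stability():
    g1 = estimate_g(2, 0.0, 50, n_mc=100_000, seed=0)
    g2 = estimate_g(2, 0.0, 50, n_mc=100_000, seed=1)
    assert abs(g1 - g2) < 0.01


def test_detection_boundary_defaults():
    # epsilon=0, l=1: m = M^0.6 detectable, m = M^0.3 not; g=0.5 never
    M = 400
    assert detection_boundary(1, 0.0, int(round(M**0.6)), M, n_mc=2000, seed=0)
    assert not detection_boundary(1, 0.0, int(round(M**0.3)), M, n_mc=2000, seed=0)
    assert not detection_boundary(1, 1.0, M, M, n_mc=20000, seed=0)


def test_evaluate_auc_matches_exact_pairwise_count():
    prob = make_planted(8, 3, l=1, epsilon=0.0, seed=2)
    rng = np.random.default_rng(3)
    for _ in range(20):
        rr = rng.permutation(8)
        cr = rng.permutation(8)
        rep = evaluate_auc(rr, prob, col_ranks=cr)
        mem = np.zeros(8, bool)
        mem[prob.rows] = True
        num = Fraction(0)
        for i in np.flatnonzero(mem):
            for j in np.flatnonzero(~mem):
                if rr[i] > rr[j]:
                    num += 1
                elif rr[i] == rr[j]:
                    num += Fraction(1, 2)
        assert Fraction(rep["A_row"]).limit_denominator(10**6) == num / (3 * 5)


def test_evaluate_auc_random_order_mean_half():
    prob = make_planted(40, 8, l=1, epsilon=0.0, seed=5)
    rng = np.random.default_rng(6)
    vals = [evaluate_auc(rng.permutation(40), prob, col_ranks=rng.permutation(40))["A_row"]
            for _ in range(500)]
    assert abs(np.mean(vals) - 0.5) < 3 * np.std(vals) / np.sqrt(len(vals))


def test_one_shot_order_spectral_recovers_strong_block():
    prob = make_planted(128, 40, l=1, epsilon=0.0, seed=7)
    rr, cr = one_shot_order(prob.D)
    assert evaluate_auc(rr, prob, col_ranks=cr)["A"] >= 0.95
    with pytest.raises(ValueError):
        one_shot_order(prob.D, method="d")
    rr2, _ = one_shot_order(prob.D, method="d", d=3)
    assert rr2.shape == (128,)


def test_phase_diagram_shape_and_determinism():
    t1 = phase_diagram(64, [8, 20], [0.0], l=1, methods=("loop", "spectral"),
                       n_trials=2, seed=4)
    t2 = phase_diagram(64, [8, 20], [0.0], l=1, methods=("loop", "spectral"),
                       n_trials=2, seed=4)
    assert len(t1) == 4
    assert set(t1.columns) >= {"m", "epsilon", "epsilon_m", "logM_m", "method", "mean_A", "n_trials"}
    assert t1.equals(t2)
    assert ((t1.mean_A >= 0) & (t1.mean_A <= 1)).all()


def test_derived_seeds_below_2_31():
    for k in range(100):
        assert 0 <= derive_seed(2**31 - 1, k) < 2**31
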