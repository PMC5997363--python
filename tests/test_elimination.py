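import warnings

import numpy as np

from loopbic._util import rank_auc
from loopbic.corrections import ContinuousCovariates
from loopbic.elimination import delineate, run_elimination, scramble_bicluster
from loopbic.planted import evaluate_auc, make_planted
from loopbic.scores import ScoreConfig, loop_scores


def _rad(rng, m, n):
    return rng.choice(np.array([-1.0, 1.0]), size=(m, n))


def test_orders_are_permutations(rng):
    D = _rad(rng, 23, 17)
    res = run_elimination(D)
    assert np.array_equal(np.sort(res.row_order), np.arange(23))
    assert np.array_equal(np.sort(res.col_order), np.arange(17))


def test_deterministic_and_monotone(rng):
    D = _rad(rng, 20, 20)
    r1 = run_elimination(D)
    r2 = run_elimination(D)
    assert np.array_equal(r1.row_order, r2.row_order)
    assert np.array_equal(r1.col_order, r2.col_order)
    assert np.allclose(r1.row_traces, r2.row_traces)
    sizes = np.array(r1.remaining_sizes)
    assert np.all(np.diff(sizes[:, 0]) < 0) and np.all(np.diff(sizes[:, 1]) < 0)


def test_gamma_controls_removal(rng):
    D = _rad(rng, 40, 40)
    res = run_elimination(D, config=ScoreConfig(gamma=0.25))
    assert len(res.removed_rows_per_iter[0]) == int(np.ceil(0.25 * 40))


def test_control_corrected_traces_bounded(rng):
    D = _rad(rng, 20, 25)
    X = _rad(rng, 12, 25)
    res = run_elimination(D, X=X)
    assert np.all(np.abs(res.row_traces) <= 2 + 1e-12)
    assert np.all(np.abs(res.col_traces) <= 2 + 1e-12)


def test_null_auc_near_half():
    aucs = []
    for seed in range(32):
        rng = np.random.default_rng(1000 + seed)
        D = _rad(rng, 60, 60)
        res = run_elimination(D)
        fake_members = rng.choice(60, size=12, replace=False)
        mask = np.zeros(60, bool)
        mask[fake_members] = True
        rr = res.row_ranks()
        aucs.append(rank_auc(rr[mask], rr[~mask]))
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_scramble_preserves_multiset_and_outside(rng):
    D = _rad(rng, 15, 15)
    rows = np.arange(5)
    cols = np.arange(6)
    out = scramble_bicluster(D, rows, cols, seed=3)
    assert np.array_equal(np.sort(out[np.ix_(rows, cols)].ravel()),
                          np.sort(D[np.ix_(rows, cols)].ravel()))
    outside = np.ones_like(D, bool)
    outside[np.ix_(rows, cols)] = False
    assert np.array_equal(out[outside], D[outside])
    # empty selection = identity
    same = scramble_bicluster(D, np.empty(0, int), np.empty(0, int), seed=3)
    assert np.array_equal(same, D)


def test_scramble_destroys_structure(rng):
    u = rng.choice([-1.0, 1.0], size=40)
    v = rng.choice([-1.0, 1.0], size=40)
    B = np.outer(u, v)
    assert np.allclose(loop_scores(B, normalized=True).z_row, 1.0)
    S = scramble_bicluster(B, np.arange(40), np.arange(40), seed=1)
    assert np.abs(loop_scores(S, normalized=True).z_row.mean()) < 0.1


def test_rerun_after_scramble_finds_second_bicluster():
    rng = np.random.default_rng(77)
    M = 150
    D = _rad(rng, M, M)
    for (r0, c0) in ((0, 0), (50, 50)):
        u = rng.choice([-1.0, 1.0], size=30)
        v = rng.choice([-1.0, 1.0], size=30)
        D[np.ix_(np.arange(r0, r0 + 30), np.arange(c0, c0 + 30))] = np.outer(u, v)
    res1 = run_elimination(D)
    s1 = delineate(res1)
    D2 = scramble_bicluster(D, s1.rows, s1.cols, seed=5)
    res2 = run_elimination(D2)
    rr = res2.row_ranks()
    first = set(s1.rows.tolist())
    # the second planted block: whichever of the two does not overlap the first find
    blocks = [set(range(0, 30)), set(range(50, 80))]
    second = min(blocks, key=lambda b: len(b & first))
    mask = np.zeros(M, bool)
    mask[list(second)] = True
    assert rank_auc(rr[mask], rr[~mask]) >= 0.9


def test_delineate_planted_alignment():
    prob = make_planted(200, 35, l=1, epsilon=0.0, seed=3)
    res = run_elimination(prob.D)
    s = delineate(res)
    assert s.rows.size >= 2 and s.cols.size >= 2
    assert s.alignment_auc is not None and s.alignment_auc >= 0.95
    assert np.all(np.abs(s.correlations) <= 1 + 1e-12)
    # most delineated members are true planted members
    assert np.intersect1d(s.rows, prob.rows).size / s.rows.size >= 0.8


def test_delineate_perfect_alignment_case():
    # member rows equal +/-v exactly inside the member columns -> |c_j| = 1
    rng = np.random.default_rng(9)
    D = _rad(rng, 80, 70)
    v = rng.choice([-1.0, 1.0], size=25)
    signs = rng.choice([-1.0, 1.0], size=20)
    D[np.ix_(np.arange(20), np.arange(25))] = np.outer(signs, v)
    res = run_elimination(D)
    s = delineate(res)
    true_members = np.intersect1d(s.rows, np.arange(20))
    assert true_members.size >= 2
    assert set(s.cols.tolist()) <= set(range(25))
    assert np.allclose(np.abs(s.correlations[true_members]), 1.0)


def test_delineate_flat_traces_warns():
    res = run_elimination(np.ones((10, 10)))
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        s = delineate(res)
    # all-ones input gives perfectly flat traces -> empty membership + warning
    assert s.rows.size == 0 and len(w) == 1


def test_covariate_aware_elimination_runs(rng):
    D = _rad(rng, 24, 20)
    cov = ContinuousCovariates(rng.standard_normal((24, 2)), kappa2=1 / 3)
    res = run_elimination(D, cov=cov)
    assert np.array_equal(np.sort(res.row_order), np.arange(24))


def test_evaluate_auc_extremes():
    prob = make_planted(30, 5, l=1, epsilon=0.0, seed=0)
    ranks = np.zeros(30, dtype=int)
    order = np.concatenate([np.setdiff1d(np.arange(30), prob.rows), prob.rows])
    ranks[order] = np.arange(30)
    cranks = np.zeros(30, dtype=int)
    corder = np.concatenate([np.setdiff1d(np.arange(30), prob.cols), prob.cols])
    cranks[corder] = np.arange(30)
    rep = evaluate_auc(ranks, prob, col_ranks=cranks)
    assert rep["A_row"] == 1.0 and rep["A"] == 1.0
    # members eliminated first -> A_row = 0
    worst = np.zeros(30, dtype=int)
    worst[np.concatenate([prob.rows, np.setdiff1d(np.arange(30), prob.rows)])] = np.arange(30)
    rep = evaluate_auc(worst, prob, col_ranks=cranks)
    assert rep["A_row"] == 0.0
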