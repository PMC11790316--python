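import numpy as np
import pandas as pd
import pytest

from gridhotspots import (
    AnnualFieldStack,
    GridLattice,
    classify_year,
    gi_star_scores,
    mc_pvalues,
    queen_neighbors,
    run_yearly,
)
from gridhotspots.gistar import draw_conditional_samples, year_seed
from oracles import naive_gi_star, brute_queen_adjacency


def _random_lattice(rng, shape=(10, 10), mask_p=0.0):
    valid = rng.random(shape) >= mask_p
    if not valid.any():
        valid[0, 0] = valid[0, 1] = True
    return GridLattice(*shape, valid)


class TestGiStarScores:
    def test_constant_field_all_degenerate(self, full_3x3):
        _, weights = full_3x3
        scores, degenerate = gi_star_scores(np.full(9, 7.0), weights)
        assert degenerate.all()
        assert np.isnan(scores).all()

    def test_3x3_matches_frozen_oracle_values(self, full_3x3):
        # values computed once with the scalar reference implementation
        lat, _ = full_3x3
        x = np.arange(1.0, 10.0)
        w_self = queen_neighbors(lat, include_self=True)
        scores, degen = gi_star_scores(x, w_self)
        assert scores[0] == pytest.approx(-1.959591794226542, rel=1e-12)
        assert degen[4]  # center neighborhood spans the whole unit: radical 0
        w_noself = queen_neighbors(lat, include_self=False)
        scores_ns, degen_ns = gi_star_scores(x, w_noself)
        assert not degen_ns.any()
        assert scores_ns[4] == pytest.approx(0.0, abs=1e-12)
        assert scores_ns[0] == pytest.approx(-1.0327955589886444, rel=1e-12)

    @pytest.mark.parametrize("include_self", [True, False])
    @pytest.mark.parametrize("mask_p", [0.0, 0.15])
    def test_matches_naive_formula_on_random_instances(self, include_self, mask_p):
        rng = np.random.default_rng(11)
        for _ in range(10):
            lat = _random_lattice(rng, mask_p=mask_p)
            weights = queen_neighbors(lat, include_self=include_self)
            x = rng.normal(50, 10, lat.n_cells)
            scores, degen = gi_star_scores(x, weights)
            exp_scores, exp_degen = naive_gi_star(x, brute_queen_adjacency(lat.valid), include_self)
            assert np.array_equal(degen, exp_degen)
            ok = ~degen
            np.testing.assert_allclose(scores[ok], exp_scores[ok], rtol=1e-10)

    def test_affine_invariance(self, full_3x3):
        lat, weights = full_3x3
        rng = np.random.default_rng(5)
        x = rng.normal(40, 8, 9)
        s1, _ = gi_star_scores(x, weights)
        s2, _ = gi_star_scores(5 + 2 * x, weights)
        ok = ~np.isnan(s1)
        np.testing.assert_allclose(s1[ok], s2[ok], rtol=1e-12)

    def test_misaligned_field_rejected(self, full_3x3):
        _, weights = full_3x3
        with pytest.raises(ValueError):
            gi_star_scores(np.zeros(5), weights)


class TestMcPvalues:
    def test_p_granularity_and_range(self):
        rng = np.random.default_rng(2)
        lat = _random_lattice(rng, shape=(8, 8))
        weights = queen_neighbors(lat)
        x = rng.normal(size=lat.n_cells)
        scores, degen = gi_star_scores(x, weights)
        p = mc_pvalues(x, weights, scores, nsim=99, seed=1, degenerate=degen)
        assert np.all(p > 0) and np.all(p <= 1)
        np.testing.assert_allclose(p * 100, np.round(p * 100), atol=1e-9)

    def test_extreme_observed_score_gets_minimum_p(self):
        # the focal cell's whole 3x3 block is spiked: a random sample of 8
        # other cells reaches the observed neighborhood sum only by drawing
        # all 8 spikes, so every simulation falls below the observed score
        lat = GridLattice(8, 8, np.ones((8, 8), bool))
        weights = queen_neighbors(lat)
        x = np.zeros(64)
        focal = 27  # (3, 3)
        block = [focal] + weights.neighbors(focal).tolist()
        x[block] = 100.0
        scores, degen = gi_star_scores(x, weights)
        p = mc_pvalues(x, weights, scores, nsim=99, seed=3, degenerate=degen)
        assert p[focal] == pytest.approx(1 / 100)

    def test_observed_below_every_simulation_gets_p_one(self):
        # focal cell is high but its observed neighborhood is the all-zero
        # worst case: every simulated draw matches or beats it, so p = 1
        lat = GridLattice(8, 8, np.ones((8, 8), bool))
        weights = queen_neighbors(lat)
        x = np.zeros(64)
        x[27] = 1000.0
        x[:10] = np.linspace(0.1, 1.0, 10)
        scores, degen = gi_star_scores(x, weights)
        assert scores[27] > 0
        p = mc_pvalues(x, weights, scores, nsim=99, seed=3, degenerate=degen)
        assert p[27] == pytest.approx(1.0)

    def test_replay_oracle_reproduces_pvalues(self):
        """An independent scalar recomputation fed the same permutation stream
        must produce identical p-values."""
        rng = np.random.default_rng(9)
        lat = _random_lattice(rng, shape=(8, 8))
        weights = queen_neighbors(lat)
        x = rng.normal(size=lat.n_cells)
        scores, degen = gi_star_scores(x, weights)
        nsim = 49
        p = mc_pvalues(x, weights, scores, nsim=nsim, seed=7, degenerate=degen)

        # replay: identical generator state and identical draw protocol
        replay_rng = np.random.default_rng(7)
        n = lat.n_cells
        counts = weights.counts
        expected = np.full(n, np.nan)
        exceed = {}
        for k in np.unique(counts[~degen]):
            cells = np.flatnonzero(~degen & (counts == k))
            sampled = draw_conditional_samples(replay_rng, cells, int(k), nsim, n)
            for row, i in enumerate(cells):
                more_extreme = 0
                for s in range(nsim):
                    perm = x.copy()
                    # place the sampled values onto i's actual neighbors
                    sim_neigh_sum = x[sampled[row, s]].sum()
                    xbar = x.mean()
                    sd = np.sqrt((x**2).mean() - xbar**2)
                    wi = k + 1
                    sim_num = x[i] + sim_neigh_sum - xbar * wi
                    obs_num = x[i] + x[weights.neighbors(i)].sum() - xbar * wi
                    if obs_num >= 0:
                        more_extreme += sim_num >= obs_num
                    else:
                        more_extreme += sim_num <= obs_num
                exceed[i] = more_extreme
        for i, cnt in exceed.items():
            expected[i] = (1 + cnt) / (1 + nsim)
        ok = ~degen
        np.testing.assert_allclose(p[ok], expected[ok], rtol=0)

    def test_seeded_runs_are_identical(self):
        rng = np.random.default_rng(21)
        lat = _random_lattice(rng, shape=(8, 8))
        weights = queen_neighbors(lat)
        x = rng.normal(size=lat.n_cells)
        scores, degen = gi_star_scores(x, weights)
        p1 = mc_pvalues(x, weights, scores, nsim=99, seed=5, degenerate=degen)
        p2 = mc_pvalues(x, weights, scores, nsim=99, seed=5, degenerate=degen)
        np.testing.assert_array_equal(p1, p2)

    def test_nsim_must_be_positive(self, full_3x3):
        _, weights = full_3x3
        with pytest.raises(ValueError):
            mc_pvalues(np.arange(9.0), weights, np.zeros(9), nsim=0, seed=1)

    def test_monotone_in_observed_extremity(self):
        """Within one cell's permutation stream, a more extreme observed score
        never receives a larger p-value."""
        rng = np.random.default_rng(13)
        lat = _random_lattice(rng, shape=(8, 8))
        weights = queen_neighbors(lat)
        x = rng.normal(size=lat.n_cells)
        n = lat.n_cells
        cell = 20
        k = int(weights.counts[cell])
        sampled = draw_conditional_samples(np.random.default_rng(17), np.array([cell]), k, 99, n)
        sim_sums = x[sampled[0]].sum(axis=1)  # one sum per simulation

        def p_of(obs_sum):
            cnt = (sim_sums >= obs_sum).sum() if obs_sum >= 0 else (sim_sums <= obs_sum).sum()
            return (1 + cnt) / 100

        grid = np.linspace(0, sim_sums.max() + 1, 50)
        ps = [p_of(v) for v in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))  # larger positive sum ⇒ p no larger
        neg = np.linspace(-1e-9, sim_sums.min() - 1, 50)  # strictly negative side
        ps_neg = [p_of(v) for v in neg]
        assert all(a >= b for a, b in zip(ps_neg, ps_neg[1:]))  # more negative ⇒ p no larger


class TestClassifyYear:
    @pytest.mark.parametrize(
        "score, p, expected",
        [(3.1, 0.01, "hotspot"), (-2.8, 0.02, "coldspot"), (0.4, 0.50, "ns")],
    )
    def test_threshold_rules(self, score, p, expected):
        out = classify_year(np.array([score]), np.array([p]), alpha=0.05)
        assert out[0] == expected

    def test_degenerate_is_ns(self):
        out = classify_year(np.array([np.nan]), np.array([np.nan]))
        assert out[0] == "ns"

    def test_strict_inequality_at_alpha(self):
        out = classify_year(np.array([2.0]), np.array([0.05]), alpha=0.05)
        assert out[0] == "ns"

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            classify_year(np.zeros(1), np.zeros(1), alpha=1.01)


class TestRunYearly:
    def test_constant_stack_all_ns(self, full_3x3):
        lat, weights = full_3x3
        stack = AnnualFieldStack(years=tuple(range(1, 13)), values=np.full((12, 9), 40.0))
        result = run_yearly(stack, weights, lat.cell_ids, seed=1)
        assert (result.table["label"] == "ns").all()
        assert result.table["degenerate"].all()

    def test_one_year_stack_equals_component_calls(self):
        rng = np.random.default_rng(8)
        lat = _random_lattice(rng, shape=(8, 8))
        weights = queen_neighbors(lat)
        x = rng.normal(40, 5, lat.n_cells)
        stack = AnnualFieldStack(years=(2008,), values=x[None, :])
        result = run_yearly(stack, weights, lat.cell_ids, nsim=99, alpha=0.05, seed=4)

        scores, degen = gi_star_scores(x, weights)
        p = mc_pvalues(x, weights, scores, nsim=99, seed=np.random.default_rng(year_seed(4, 0)), degenerate=degen)
        labels = classify_year(scores, p, alpha=0.05, degenerate=degen)
        sub = result.table
        np.testing.assert_allclose(sub["gi_score"].to_numpy(), scores)
        np.testing.assert_allclose(sub["p_value"].to_numpy(), p)
        assert (sub["label"].to_numpy() == labels).all()

    def test_repeated_execution_is_bit_identical(self):
        rng = np.random.default_rng(30)
        lat = _random_lattice(rng, shape=(12, 12))
        weights = queen_neighbors(lat)
        values = rng.normal(40, 5, (4, lat.n_cells))
        stack = AnnualFieldStack(years=(1, 2, 3, 4), values=values)
        t1 = run_yearly(stack, weights, lat.cell_ids, seed=99).table
        t2 = run_yearly(stack, weights, lat.cell_ids, seed=99).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_stack_from_long_round_trip(self, full_3x3):
        lat, _ = full_3x3
        rng = np.random.default_rng(1)
        stack = AnnualFieldStack(years=(1, 2), values=rng.normal(size=(2, 9)))
        back = AnnualFieldStack.from_long(stack.to_long(lat.cell_ids), lat.cell_ids)
        np.testing.assert_allclose(back.values, stack.values)
        assert back.years == stack.years
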