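import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perturbsim import (
    InputSpec,
    MetaPathwayGraph,
    NodeRecord,
    PolarGaussian,
    RandomizationEnsemble,
    empirical_pvalues,
    qvalues,
    randomize_input,
    run_significance,
    run_simulation,
    toy_cascade,
)


def make_ensemble(values):
    keys = (("node", "x"),)
    return RandomizationEnsemble(keys, np.asarray(values, dtype=float).reshape(-1, 1))


class TestRandomizeInput:
    def test_preserves_direction_multiset(self, fork_graph):
        spec = InputSpec(directions={"a": 1, "b": -1, "c": -1})
        rnd = randomize_input(fork_graph, spec, np.random.default_rng(0))
        assert sorted(rnd.directions.values()) == [-1, -1, 1]
        assert len(rnd.directions) == 3

    def test_exhaustive_when_graph_has_exactly_n_nodes(self, fork_graph):
        spec = InputSpec(directions={"a": 1, "b": 1, "c": -1})
        rnd = randomize_input(fork_graph, spec, np.random.default_rng(0))
        assert set(rnd.directions) == {"a", "b", "c"}

    def test_too_few_candidates_raises(self, fork_graph):
        spec = InputSpec(directions={"a": 1, "b": 1, "c": -1})
        g = MetaPathwayGraph([NodeRecord("a"), NodeRecord("b")])
        with pytest.raises(ValueError, match="candidate"):
            randomize_input(g, spec, np.random.default_rng(0))

    def test_virtual_nodes_excluded(self):
        g = MetaPathwayGraph(
            [NodeRecord("a"), NodeRecord("v", category="virtual")]
        )
        spec = InputSpec(directions={"a": 1})
        for seed in range(5):
            rnd = randomize_input(g, spec, np.random.default_rng(seed))
            assert set(rnd.directions) == {"a"}

    def test_nonexpressed_list_carried_over(self, fork_graph):
        spec = InputSpec(directions={"a": 1}, nonexpressed={"zz"})
        rnd = randomize_input(fork_graph, spec, np.random.default_rng(0))
        assert rnd.nonexpressed == {"zz"}

    def test_different_streams_give_different_sets(self):
        ids = [f"n{i:03d}" for i in range(100)]
        g = MetaPathwayGraph([NodeRecord(i) for i in ids])
        spec = InputSpec(directions={ids[0]: 1, ids[1]: -1, ids[2]: 1})
        draws = {
            tuple(sorted(randomize_input(g, spec, np.random.default_rng(s)).directions))
            for s in range(20)
        }
        assert len(draws) > 1


class TestEmpiricalPvalues:
    def test_no_exceedance_gives_zero(self):
        p = empirical_pvalues({("node", "x"): 5.0}, make_ensemble([1, 2, 3, 4]))
        assert p[("node", "x")] == 0.0

    def test_half_exceedance(self):
        p = empirical_pvalues({("node", "x"): 5.0}, make_ensemble([6, 6, 1, 1]))
        assert p[("node", "x")] == 0.5

    def test_zero_observed_full_exceedance(self):
        p = empirical_pvalues({("node", "x"): 0.0}, make_ensemble([0.1, -3, 2, -1]))
        assert p[("node", "x")] == 1.0

    def test_abs_mode_treats_inhibition_as_signal(self):
        # strongly negative observed score: raw comparison calls it null,
        # magnitude comparison does not
        ens = make_ensemble([1.0, 2.0, -1.0, 0.5])
        raw = empirical_pvalues({("node", "x"): -8.0}, ens, mode="raw")
        mag = empirical_pvalues({("node", "x"): -8.0}, ens, mode="abs")
        assert raw[("node", "x")] == 1.0
        assert mag[("node", "x")] == 0.0

    def test_uncovered_entity_raises(self):
        with pytest.raises(KeyError):
            empirical_pvalues({("node", "y"): 1.0}, make_ensemble([1.0]))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalues({("node", "x"): 1.0}, make_ensemble([1.0]), mode="both")


def brute_force_step_up(p, pi0):
    """Independent oracle: literal min-over-j>=i of pi0*m*p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(
            min(pi0 * m * p[order[j - 1]] / j for j in range(pos, m + 1)), 1.0
        )
    return q


class TestQvalues:
    def test_matches_brute_force_with_forced_pi0(self):
        p = [0.01, 0.02, 0.03]
        assert qvalues(p, pi0=1.0) == pytest.approx([0.03, 0.03, 0.03])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_agrees_with_oracle_and_is_monotone(self, p):
        q = qvalues(p, pi0=1.0)
        assert q == pytest.approx(brute_force_step_up(p, 1.0))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_all_ones(self):
        assert qvalues([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_is_pi0_times_p(self):
        assert qvalues([0.2], pi0=0.5) == pytest.approx([0.1])

    def test_pi0_estimated_at_lambda(self):
        # 4 of 8 p-values above 0.5 -> pi0 = 4 / (0.5 * 8) = 1.0
        p = [0.01, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9]
        assert qvalues(p)[0] == pytest.approx(qvalues(p, pi0=1.0)[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestRunSignificance:
    def gaussian(self, seed=0):
        return PolarGaussian(np.random.default_rng(seed))

    def test_single_randomization_yields_binary_p(self, fork_graph):
        spec = InputSpec(directions={"a": 1})
        obs = run_simulation(fork_graph, spec, 20, self.gaussian())
        sig = run_significance(
            fork_graph, spec, obs, R=1, T_inner=10, rng=np.random.default_rng(1)
        )
        assert set(sig.p_values.values()) <= {0.0, 1.0}

    def test_input_nodes_score_low_p_on_cascade(self):
        g = toy_cascade(depth=3, branching=2)
        spec = InputSpec(directions={"root": 1})
        rng = np.random.default_rng(4)
        obs = run_simulation(g, spec, 200, PolarGaussian(rng))
        sig = run_significance(g, spec, obs, R=100, T_inner=50, rng=rng)
        node_ps = [v for (lvl, _), v in sig.p_values.items() if lvl == "node"]
        median_p = float(np.median(node_ps))
        assert sig.p_values[("node", "root")] <= median_p
        assert sig.p_values[("node", "d1_000")] <= median_p

    def test_zero_observed_scores_count_nonzero_nulls(self, fork_graph):
        empty = InputSpec()
        obs = run_simulation(fork_graph, empty, 10, self.gaussian())
        spec = InputSpec(directions={"a": 1})
        rng = np.random.default_rng(2)
        sig = run_significance(fork_graph, spec, obs, R=40, T_inner=10, rng=rng)
        # observed scores are all 0, so p = fraction of randomizations with
        # nonzero score, per entity; for node a-or-upstream entities that is high
        assert all(0 <= v <= 1 for v in sig.p_values.values())
        assert sig.p_values[("node", "b")] > 0.5

    def test_p_values_on_grid_and_q_monotone(self, fork_graph):
        spec = InputSpec(directions={"a": 1})
        obs = run_simulation(fork_graph, spec, 20, self.gaussian())
        sig = run_significance(
            fork_graph, spec, obs, R=25, T_inner=10, rng=np.random.default_rng(3)
        )
        grid = {i / 25 for i in range(26)}
        assert set(sig.p_values.values()) <= grid
        keys = sorted(sig.p_values, key=lambda k: sig.p_values[k])
        qs = [sig.q_values[k] for k in keys]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_bitwise_reproducible_given_seed(self, fork_graph):
        spec = InputSpec(directions={"a": 1, "b": -1})
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            obs = run_simulation(fork_graph, spec, 30, PolarGaussian(rng))
            runs.append(
                run_significance(fork_graph, spec, obs, R=15, T_inner=10, rng=rng)
            )
        assert runs[0].p_values == runs[1].p_values
        assert runs[0].q_values == runs[1].q_values
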