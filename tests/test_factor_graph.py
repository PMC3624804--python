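import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spedre import (
    DiscretizationScheme,
    ErrorTermIndex,
    TimeSeriesDataset,
    build_bins,
    build_factor_graph,
    compute_joint_table,
    error_term,
    make_ring_network,
    make_ring_scenario,
    generate_dataset,
    max_marginalize,
    parse_network,
    run_lbp,
    simulate,
    spedre_base,
    table_argmax,
)
from spedre.factor_graph import FactorGraph, FactorNode, JointTable, attach_joint_tables
from spedre.splines import DerivativeTable, interpolated_derivatives


class TestBuildBins:
    def test_canonical_binning(self):
        bins = build_bins(0.05, 1.05, 10)
        assert bins.width == pytest.approx(0.1)
        np.testing.assert_allclose(bins.midpoints, np.arange(1, 11) / 10, atol=1e-12)

    def test_two_bins(self):
        np.testing.assert_allclose(build_bins(0, 1, 2).midpoints, [0.25, 0.75])

    def test_single_bin_warns(self):
        with pytest.warns(RuntimeWarning):
            bins = build_bins(0, 1, 1)
        assert bins.midpoints == pytest.approx([0.5])

    def test_invalid(self):
        with pytest.raises(ValueError):
            build_bins(1.0, 1.0, 4)
        with pytest.raises(ValueError):
            build_bins(0, 1, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lower=st.floats(-10, 10),
        width=st.floats(0.01, 5),
        count=st.integers(2, 50),
    )
    def test_midpoints_strictly_inside(self, lower, width, count):
        bins = build_bins(lower, lower + width, count)
        assert np.all(bins.midpoints > bins.lower)
        assert np.all(bins.midpoints < bins.upper)
        assert np.allclose(np.diff(bins.midpoints), bins.width)


def _dataset_for(net, params, x0, n_t=11):
    traj = simulate(net, params, x0, np.linspace(0, 4, n_t))
    return TimeSeriesDataset.from_trajectories(net.species_names, [traj])


class TestBuildFactorGraph:
    def test_reversible_pair_counts(self, ab_problem):
        net, _, ds = ab_problem
        g = build_factor_graph(net, ds)
        assert len(g.factors) == 22  # 2 species x 11 timepoints
        assert all(node.param_indices == (0, 1) for node in g.factors)
        assert g.n_variables == 2

    def test_single_species_degree_one(self):
        net = parse_network("A -> ; k")
        ds = _dataset_for(net, np.array([0.5]), np.array([1.0]), n_t=5)
        g = build_factor_graph(net, ds)
        assert len(g.factors) == 5
        assert all(len(node.param_indices) == 1 for node in g.factors)

    def test_ring_counts(self):
        net = make_ring_network(10)
        rng = np.random.default_rng(0)
        ds = _dataset_for(net, rng.uniform(0.1, 1, 10), rng.uniform(0.1, 1, 10))
        g = build_factor_graph(net, ds)
        assert len(g.factors) == 110
        assert all(len(node.param_indices) == 2 for node in g.factors)


class TestJointTable:
    def test_boltzmann_two_cell_table(self):
        # 1-D factor A -> 0 with bins {0.5, 1.5} and derivative -0.5 at A=1:
        # epsilon = {0, 1}; beta=1 gives {1, 1/e} normalized.
        net = parse_network("A -> ; k")
        ds = TimeSeriesDataset(
            species_names=["A"], experiments=["e0"],
            timepoints=[np.array([0.0, 1.0])], observations=[np.ones((2, 1))],
        )
        derivs = DerivativeTable(
            derivatives=[np.full((2, 1), -0.5)], concentrations=[np.ones((2, 1))]
        )
        scheme = DiscretizationScheme.uniform(1, 0.0, 2.0, 2)
        table = compute_joint_table(ErrorTermIndex(0, 0, 0), net, ds, derivs, scheme, beta=1.0)
        expected = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(table.probs, expected / expected.sum())

    def test_constant_error_gives_uniform_table(self):
        # catalyst-only ODE term cancels: epsilon is flat in k
        net = parse_network("E + S -> E + P ; k")
        ds = TimeSeriesDataset(
            species_names=["E", "S", "P"], experiments=["e0"],
            timepoints=[np.array([0.0, 1.0])], observations=[np.ones((2, 3))],
        )
        derivs = DerivativeTable(
            derivatives=[np.zeros((2, 3))], concentrations=[np.ones((2, 3))]
        )
        scheme = DiscretizationScheme.uniform(1, 0.05, 1.05, 4)
        table = compute_joint_table(ErrorTermIndex(0, 0, 0), net, ds, derivs, scheme)
        np.testing.assert_allclose(table.probs, 0.25)

    def test_grid_matches_per_cell_error_term(self):
        """Dual route: vectorized grid tables equal cell-by-cell evaluation."""
        scen, scheme = make_ring_scenario(3, seed=5)
        ds = generate_dataset(scen)
        derivs = interpolated_derivatives(ds)
        net = scen.network
        g = build_factor_graph(net, ds, scheme)
        attach_joint_tables(g, ds, derivs, beta=1.0)
        node = g.factors[7]
        e, i, j = node.index
        for combo in itertools.product(*(range(scheme.bins[p].count) for p in node.param_indices)):
            params = scen.nominal_params.copy()
            for p, b in zip(node.param_indices, combo):
                params[p] = scheme.midpoints(p)[b]
            eps = error_term(net, params, ds, derivs, node.index)
            assert node.table.probs[combo] == pytest.approx(
                np.exp(-eps) / np.sum(np.exp(-_grid(node, scheme, net, ds, derivs))), rel=1e-9
            )

    def test_tables_normalized_and_underflow_safe(self):
        scen, scheme = make_ring_scenario(4, seed=2)
        ds = generate_dataset(scen)
        derivs = interpolated_derivatives(ds)
        g = build_factor_graph(scen.network, ds, scheme)
        attach_joint_tables(g, ds, derivs, beta=1e9)  # extreme contrast: raw weights underflow
        for node in g.factors:
            assert node.table.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(node.table.probs >= 0)


def _grid(node, scheme, net, ds, derivs):
    from spedre.factor_graph import _grid_error_terms

    return _grid_error_terms(node.index, node.param_indices, net, derivs, scheme)


class TestArgmaxAndMaxMarginalize:
    def _table(self, probs):
        probs = np.asarray(probs, dtype=float)
        return JointTable(
            factor=ErrorTermIndex(0, 0, 0),
            param_indices=tuple(range(probs.ndim)),
            probs=probs,
            log_probs=np.log(probs + 1e-300),
            beta=1.0,
        )

    def test_uniform_tie_breaks_to_first_cell(self):
        assert table_argmax(self._table(np.full((3, 3), 1 / 9))) == (0, 0)

    def test_one_dimensional(self):
        assert table_argmax(self._table([0.2, 0.5, 0.3])) == (1,)

    def test_matches_exhaustive_scan_3d(self):
        rng = np.random.default_rng(11)
        probs = rng.random((3, 3, 3))
        probs /= probs.sum()
        best = max(
            itertools.product(range(3), repeat=3), key=lambda c: (probs[c], [-x for x in c])
        )
        assert table_argmax(self._table(probs)) == best

    def test_max_marginalize_hand_case(self):
        np.testing.assert_allclose(max_marginalize(np.array([[1, 2], [3, 4]]), 0), [2, 4])
        np.testing.assert_allclose(max_marginalize(np.array([[1, 2], [3, 4]]), 1), [3, 4])

    def test_identity_and_constant(self):
        v = np.array([1.0, 5.0, 2.0])
        np.testing.assert_allclose(max_marginalize(v, 0), v)
        np.testing.assert_allclose(max_marginalize(np.full((2, 3), 7.0), 1), [7, 7, 7])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2), st.integers(0, 10_000))
    def test_matches_brute_force(self, keep, seed):
        rng = np.random.default_rng(seed)
        g = rng.random((3, 4, 2))
        expected = np.array(
            [
                max(
                    g[tuple(np.insert(np.array(rest), keep, b))]
                    for rest in itertools.product(
                        *(range(s) for a, s in enumerate(g.shape) if a != keep)
                    )
                )
                for b in range(g.shape[keep])
            ]
        )
        np.testing.assert_allclose(max_marginalize(g, keep), expected)


def _single_factor_graph(probs):
    net = parse_network("A -> B ; k1\nB -> C ; k2")
    scheme = DiscretizationScheme.uniform(2, 0.0, 1.0, probs.shape[0])
    table = JointTable(
        factor=ErrorTermIndex(0, 1, 0),
        param_indices=(0, 1),
        probs=probs,
        log_probs=np.log(probs),
        beta=1.0,
    )
    return FactorGraph(
        network=net,
        scheme=scheme,
        factors=[FactorNode(ErrorTermIndex(0, 1, 0), (0, 1), table)],
        var_factors=[[0], [0]],
    )


class TestRunLbp:
    def test_single_factor_exact(self):
        rng = np.random.default_rng(0)
        probs = rng.random((4, 4))
        probs /= probs.sum()
        g = _single_factor_graph(probs)
        result = run_lbp(g)
        assert tuple(result.bins) == table_argmax(g.factors[0].table)

    def test_messages_and_beliefs_are_distributions(self, ring10_problem):
        scenario, scheme, dataset = ring10_problem
        derivs = interpolated_derivatives(dataset)
        g = build_factor_graph(scenario.network, dataset, scheme)
        attach_joint_tables(g, dataset, derivs)
        result = run_lbp(g)
        for belief in result.beliefs:
            assert belief.sum() == pytest.approx(1.0, abs=1e-12)
        for per_var in g.message_history:
            for msg in per_var.values():
                assert np.exp(msg).sum() == pytest.approx(1.0, abs=1e-12)

    def test_tables_never_mutated_by_propagation(self, ring10_problem):
        scenario, scheme, dataset = ring10_problem
        derivs = interpolated_derivatives(dataset)
        g = build_factor_graph(scenario.network, dataset, scheme)
        attach_joint_tables(g, dataset, derivs)
        before = [node.table.probs.copy() for node in g.factors]
        run_lbp(g)
        for node, saved in zip(g.factors, before):
            np.testing.assert_array_equal(node.table.probs, saved)

    def test_empty_graph_rejected(self):
        net = parse_network("A -> B ; k")
        g = FactorGraph(
            network=net,
            scheme=DiscretizationScheme.uniform(1, 0, 1, 2),
            factors=[],
            var_factors=[[]],
        )
        with pytest.raises(ValueError):
            run_lbp(g)

    def test_tiny_cyclic_graph_matches_exhaustive_minimum(self):
        """Well-separated instance: LBP equals the brute-force best combination."""
        from spedre import error_terms

        scen, _ = make_ring_scenario(3, seed=1)
        scheme = DiscretizationScheme.uniform(3, 0.05, 1.05, 4)
        from spedre.benchmarks import snap_to_midpoints, BenchmarkScenario

        nominal = snap_to_midpoints(scen.nominal_params, scheme)
        scen = BenchmarkScenario(
            network=scen.network, nominal_params=nominal,
            timepoints=scen.timepoints, seed=scen.seed,
        )
        ds = generate_dataset(scen)
        derivs = interpolated_derivatives(ds)
        g = build_factor_graph(scen.network, ds, scheme)
        attach_joint_tables(g, ds, derivs)
        result = run_lbp(g)
        best = min(
            itertools.product(range(4), repeat=3),
            key=lambda c: np.sum(
                np.log(
                    np.maximum(
                        error_terms(scen.network, scheme.midpoint_vector(np.array(c)), ds, derivs),
                        1e-12,
                    )
                )
            ),
        )
        assert tuple(result.bins) == best


class TestSpedreBase:
    def test_reversible_pair_exact_recovery(self, ab_problem):
        net, params, ds = ab_problem  # truth at midpoints of the canonical bins
        scheme = DiscretizationScheme.uniform(2, 0.05, 1.05, 10)
        result = spedre_base(net, ds, scheme)
        np.testing.assert_allclose(result.midpoints, params)

    def test_equilibrium_dataset_flagged_degenerate(self, ab_network):
        ds = TimeSeriesDataset(
            species_names=["A", "B"], experiments=["e0"],
            timepoints=[np.linspace(0, 4, 11)],
            observations=[np.tile([0.5, 0.5], (11, 1))],
        )
        scheme = DiscretizationScheme.uniform(2, 0.05, 1.05, 10)
        with pytest.warns(RuntimeWarning, match="weakly identified"):
            result = spedre_base(ab_network, ds, scheme)
        assert result.weak_parameters  # equilibrium data cannot separate k1 from k2

    def test_deterministic_repeat(self, ring10_problem):
        scenario, scheme, dataset = ring10_problem
        a = spedre_base(scenario.network, dataset, scheme)
        b = spedre_base(scenario.network, dataset, scheme)
        np.testing.assert_array_equal(a.bins, b.bins)
        for ba, bb in zip(a.beliefs, b.beliefs):
            np.testing.assert_array_equal(ba, bb)

    def test_cell_count_matches_degree_formula(self, ring10_problem):
        scenario, scheme, dataset = ring10_problem
        result = spedre_base(scenario.network, dataset, scheme)
        # 10 species x 9 interior timepoints, every factor degree 2 with 10 bins
        assert result.cells_computed == 90 * 10**2

    def test_boundary_timepoints_can_be_included(self, ring10_problem):
        scenario, scheme, dataset = ring10_problem
        result = spedre_base(scenario.network, dataset, scheme, use_boundary_timepoints=True)
        assert result.cells_computed == 110 * 10**2
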