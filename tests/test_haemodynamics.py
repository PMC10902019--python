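"""Rheology, the quasi-steady network solver, and GCI arithmetic."""

import numpy as np
import pytest

import cowflow as cf
from conftest import random_flow_network


def const_flow(value=300.0, n=32):
    return cf.SampledWaveform(np.full(n, value), 1.0, "mL/min")


def solve(net, table, inflow, rheology=None, **cfg_kw):
    flows = {"LICA": inflow}
    splits = cf.build_outlet_splits(net, flows, table)
    rheo = rheology if rheology is not None else cf.RheologyParams()
    return cf.solve_network(net, flows, splits, rheo, cf.SolverConfig(**cfg_kw))


class TestCarreauYasuda:
    def test_zero_shear_limit(self):
        assert cf.carreau_yasuda_viscosity(0.0) == pytest.approx(0.022, rel=1e-12)

    def test_infinite_shear_limit(self):
        assert cf.carreau_yasuda_viscosity(1e12) == pytest.approx(0.0022, rel=1e-4)

    def test_characteristic_shear_value(self):
        # direct formula at lambda*gamma = 1:
        # 0.0022 + 0.0198 * 2^((0.392-1)/0.644)
        expected = 0.0022 + 0.0198 * 2.0 ** ((0.392 - 1.0) / 0.644)
        assert cf.carreau_yasuda_viscosity(1 / 0.11) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.012491127487818538, rel=1e-12)

    def test_strictly_decreasing(self):
        gammas = np.logspace(-3, 6, 200)
        mus = cf.carreau_yasuda_viscosity(gammas)
        assert np.all(np.diff(mus) < 0)
        assert np.all(mus > 0.0022) and np.all(mus < 0.022)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            cf.carreau_yasuda_viscosity(-1.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            cf.RheologyParams(eta_inf=0.03, eta_0=0.022)


class TestSolveNetworkOracles:
    def test_single_tube_poiseuille(self, single_tube):
        net, table = single_tube
        mu = 0.0035
        sol = solve(net, table, const_flow(300.0), cf.RheologyParams.newtonian(mu),
                    reference_node="B")
        q = 300e-6 / 60
        d, length = 4e-3, 0.1
        dp = 128 * mu * length * q / (np.pi * d**4)
        v_max = 2 * q / (np.pi * d**2 / 4)
        assert sol.node_pressure("A").values == pytest.approx(dp, rel=1e-9)
        assert sol.segment_v_max("T").values == pytest.approx(v_max * 100, rel=1e-9)
        assert sol.segment_wss("T").values == pytest.approx(
            32 * mu * q / (np.pi * d**3), rel=1e-9
        )

    def test_symmetric_y_splits_equally(self, symmetric_y):
        net, table = symmetric_y
        sol = solve(net, table, const_flow(400.0))
        assert np.allclose(
            sol.segment_flow("D1").values, sol.segment_flow("D2").values, rtol=1e-12
        )
        assert np.allclose(
            sol.node_pressure("B1").values, sol.node_pressure("B2").values, rtol=1e-9, atol=1e-9
        )
        assert np.allclose(sol.segment_flow("P").values, 400.0, rtol=1e-9)

    def test_newtonian_tree_resistance_oracle(self):
        """On a tree, segment flows follow from conservation alone and
        pressures from summing R*Q along root paths — an oracle independent
        of the Laplacian solve."""
        rng = np.random.default_rng(42)
        mu = 0.004
        for _ in range(10):
            net, table = random_flow_network(rng, n_extra=4)
            flows = {"LICA": const_flow(500.0)}
            splits = cf.build_outlet_splits(net, flows, table)
            sol = cf.solve_network(
                net, flows, splits, cf.RheologyParams.newtonian(mu),
                cf.SolverConfig(reference_node="n0"),
            )
            # oracle: accumulate outlet demands up the tree
            children: dict[str, list] = {}
            for s in net.segments:
                children.setdefault(s.from_node, []).append(s)

            def subtree_outflow(node):
                total = np.zeros(32)
                if node in net.outlets:
                    total += splits.flows[node].values * 1e-6 / 60
                for s in children.get(node, []):
                    total += subtree_outflow(s.to_node)
                return total

            for s in net.segments:
                expected = subtree_outflow(s.to_node)
                got = sol.segment_flow(s.id).values * 1e-6 / 60
                assert np.allclose(got, expected, rtol=1e-9, atol=1e-18)
            # pressure drop along each segment equals R*Q
            for s in net.segments:
                r = 128 * mu * (s.length_mm * 1e-3) / (np.pi * (s.diameter_mm * 1e-3) ** 4)
                q = sol.segment_flow(s.id).values * 1e-6 / 60
                dp = sol.node_pressure(s.from_node).values - sol.node_pressure(s.to_node).values
                assert np.allclose(dp, r * q, rtol=1e-9, atol=1e-9)


class TestSolveNetworkInvariants:
    def test_conservation_and_viscosity_bounds(self, small_cohort):
        p = small_cohort[0]
        sol = p.sim_results["rest"].solution
        rheo = cf.RheologyParams()
        assert np.all(sol.mu_pa_s >= rheo.eta_inf - 1e-15)
        assert np.all(sol.mu_pa_s <= rheo.eta_0 + 1e-15)
        assert np.allclose(sol.v_max_cm_s, 2 * sol.v_mean_cm_s, rtol=1e-14)

    def test_random_networks_conserve_mass(self):
        rng = np.random.default_rng(3)
        for i in range(20):
            net, table = random_flow_network(rng, n_extra=5, with_loop=(i % 2 == 0))
            flows = {"LICA": const_flow(600.0)}
            splits = cf.build_outlet_splits(net, flows, table)
            sol = cf.solve_network(net, flows, splits)
            # mass conservation at every node and phase: signed segment
            # flows out of each interior node sum to zero
            node_net = {n: np.zeros(32) for n in net.nodes}
            for s in net.segments:
                q = sol.segment_flow(s.id).values
                node_net[s.from_node] += q
                node_net[s.to_node] -= q
            for n in net.nodes:
                inj = np.zeros(32)
                if n in net.inlets:
                    inj += flows[net.inlets[n]].values
                if n in net.outlets:
                    inj -= splits.flows[n].values
                assert np.allclose(node_net[n], inj, rtol=1e-9, atol=1e-6)

    def test_reference_node_invariance(self, symmetric_y):
        net, table = symmetric_y
        sol_a = solve(net, table, const_flow(), reference_node="A")
        sol_b = solve(net, table, const_flow(), reference_node="B1")
        for seg in ("P", "D1", "D2"):
            assert np.allclose(
                sol_a.segment_flow(seg).values, sol_b.segment_flow(seg).values, rtol=1e-9
            )
        # pressures agree up to the pinned constant
        shift = sol_a.node_pressure("B1").values - sol_b.node_pressure("B1").values
        for node in ("A", "J", "B2"):
            assert np.allclose(
                sol_a.node_pressure(node).values - sol_b.node_pressure(node).values,
                shift, rtol=1e-6, atol=1e-6,
            )

    def test_phase_locality(self, symmetric_y):
        net, table = symmetric_y
        phi = np.arange(32) / 32
        pulsed = cf.SampledWaveform(400 + 150 * np.sin(2 * np.pi * phi), 1.0, "mL/min")
        perm = np.random.default_rng(0).permutation(32)
        permuted = cf.SampledWaveform(pulsed.values[perm], 1.0, "mL/min")
        sol = solve(net, table, pulsed)
        sol_perm = solve(net, table, permuted)
        assert np.allclose(
            sol_perm.segment_v_max("D1").values, sol.segment_v_max("D1").values[perm], rtol=1e-9
        )

    def test_shear_thinning_flow_monotonicity(self, symmetric_y):
        net, table = symmetric_y
        mu_low = solve(net, table, const_flow(200.0)).mu_pa_s
        mu_high = solve(net, table, const_flow(800.0)).mu_pa_s
        assert np.all(mu_high <= mu_low + 1e-15)

    def test_nonconservative_boundaries_rejected(self, symmetric_y):
        net, table = symmetric_y
        flows = {"LICA": const_flow(400.0)}
        splits = cf.build_outlet_splits(net, flows, table)
        bad = {"LICA": const_flow(500.0)}  # inflow no longer matches outlets
        with pytest.raises(ValueError):
            cf.solve_network(net, bad, splits)


class TestPoiseuilleWss:
    def test_hand_value(self):
        # tau_w = 32 * 0.0035 * 5e-6 / (pi * 6.4e-8)
        assert cf.poiseuille_wss(300.0, 4.0, 0.0035) == pytest.approx(
            32 * 0.0035 * 5e-6 / (np.pi * 6.4e-8), rel=1e-12
        )

    def test_zero_flow(self):
        assert cf.poiseuille_wss(0.0, 4.0, 0.0035) == 0.0

    def test_cubic_diameter_scaling(self):
        assert cf.poiseuille_wss(300.0, 8.0, 0.0035) == pytest.approx(
            cf.poiseuille_wss(300.0, 4.0, 0.0035) / 8, rel=1e-12
        )


class TestGci:
    def test_identical_grids(self):
        res = cf.gci(cf.GCIInput(2.5, 2.5, 2.0, 2.0))
        assert res.gci == 0.0 and res.passed

    def test_hand_arithmetic(self):
        res = cf.gci(cf.GCIInput(1.0, 1.02, 2.0, 2.0, safety_factor=1.25))
        assert res.gci == pytest.approx(0.0083333, rel=1e-4)
        assert res.passed

    def test_three_percent_criterion(self):
        # construct coarse values giving GCI exactly 0.029 and 0.031
        for target, expect_pass in ((0.029, True), (0.031, False)):
            f_coarse = 1.0 + target * 3.0 / 1.25
            res = cf.gci(cf.GCIInput(1.0, f_coarse, 2.0, 2.0))
            assert res.gci == pytest.approx(target, rel=1e-12)
            assert res.passed is expect_pass

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cf.GCIInput(0.0, 1.0, 2.0, 2.0)
        with pytest.raises(ValueError):
            cf.GCIInput(1.0, 1.0, 1.0, 2.0)
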