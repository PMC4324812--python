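"""Flow solver oracles: Poiseuille closed forms, Starling leak bookkeeping,
Darcy interstitium, rheology laws, shear stress."""
import numpy as np
import pytest

from oxynet import (phase_separation, picard_couple_flow,
                    relative_viscosity_invivo, solve_interstitial_pressure,
                    solve_network_flow, viscosity, wall_shear_stress)
from oxynet.config import FlowParams, GridSpec
from oxynet.hemodynamics import (FlowState, baseline_wss_reference,
                                 haematocrit_sweep, node_flow_residuals)

from conftest import line_network, y_bifurcation_network


def _solve_line(net, params, mu=1.0e-5):
    P_i = np.zeros(net.grid.shape)
    mu_seg = np.full(net.n_segments, mu)
    return solve_network_flow(net, params, P_i, mu_seg)


class TestPoiseuille:
    def test_single_vessel_closed_form(self):
        """Q = πR⁴ΔP/(8µL) on a straight vessel without leakage."""
        net = line_network(n_segments=8, radius=5.0, Lp=0.0)
        params = FlowParams()
        mu = 1.1e-5
        node_P, Qv, Qt = _solve_line(net, params, mu=mu)
        L = net.n_segments * net.grid.spacing
        expected = (np.pi * 5.0 ** 4 * params.delta_P_drive) / (8 * mu * L)
        assert np.allclose(Qv, expected, rtol=1e-10)
        assert np.allclose(Qt, 0.0)

    def test_series_conductance_mixed_radii(self):
        """Series resistances of unequal segments match the closed form."""
        net = line_network(n_segments=6, radius=5.0, Lp=0.0)
        radii = np.array([5.0, 4.0, 6.0, 5.0, 3.5, 8.0])
        net.radius[:] = radii
        params = FlowParams()
        mu = 9.0e-6
        node_P, Qv, _ = _solve_line(net, params, mu=mu)
        dl = net.grid.spacing
        resist = np.sum(8 * mu * dl / (np.pi * radii ** 4))
        expected = params.delta_P_drive / resist
        assert np.allclose(Qv, expected, rtol=1e-10)

    def test_symmetric_bifurcation_splits_evenly(self):
        net = y_bifurcation_network()
        params = FlowParams()
        node_P, Qv, _ = _solve_line(net, params)
        q_parent = Qv[0]
        assert q_parent > 0
        # segments 2 and 3 are the two junction arms
        assert Qv[2] == pytest.approx(q_parent / 2, rel=1e-10)
        assert abs(Qv[3]) == pytest.approx(q_parent / 2, rel=1e-10)

    def test_leaky_vessel_flow_deficit_equals_total_leak(self):
        """With P_v − P_i > σΔπ everywhere, outlet flow < inlet flow and
        the deficit equals Σ Q_t (checked segment by segment)."""
        net = line_network(n_segments=6, radius=5.0, Lp=1.0e-3)
        params = FlowParams()
        node_P, Qv, Qt = _solve_line(net, params)
        assert np.all(Qt > 0)
        # axial flow decreases downstream (segment index j is upstream of
        # j-1); the drop across each interior node equals the half-leaks
        # of its two adjacent segments
        # (the drop is ~1e-6 of the axial flow, so the comparison is
        # cancellation-limited)
        for j in range(1, 6):
            drop = Qv[j] - Qv[j - 1]
            assert drop == pytest.approx(0.5 * (Qt[j - 1] + Qt[j]),
                                         rel=1e-5)
        state = FlowState(node_P=node_P, Qv=Qv, Qt=Qt,
                          U_v=np.zeros_like(Qv), H=np.zeros_like(Qv),
                          mu=np.zeros_like(Qv), tau=np.zeros_like(Qv),
                          P_i=np.zeros(net.grid.shape),
                          U_i=np.zeros(net.grid.shape + (3,)))
        inflow, outflow = state.inflow_outflow(net)
        assert inflow - outflow == pytest.approx(Qt.sum(), rel=1e-6)
        assert outflow < inflow


class TestInterstitial:
    def test_no_vessels_gives_zero_field(self):
        net = line_network(4, Lp=0.0)
        net.collapsed[:] = True
        P, U = solve_interstitial_pressure(net, FlowParams(),
                                           np.zeros(net.n_nodes))
        assert np.all(P == 0.0) and np.all(U == 0.0)

    def test_source_flux_balance(self):
        """No-flux boundaries: the net transvascular source integrates to
        zero at the discrete level (divergence theorem)."""
        net = line_network(6, radius=5.0, Lp=1.0e-3)
        params = FlowParams()
        node_P = np.linspace(params.P_outlet + params.delta_P_drive,
                             params.P_outlet, net.n_nodes)
        P, _ = solve_interstitial_pressure(net, params, node_P)
        from oxynet.hemodynamics import vessel_voxel_sources
        vox, Lp_vox, Pv_vox = vessel_voxel_sources(net, node_P)
        src = (Lp_vox * params.S_over_V
               * (Pv_vox - P.reshape(-1)[vox] - params.osmotic_term))
        total = src.sum() * net.grid.voxel_volume
        scale = np.abs(src * net.grid.voxel_volume).sum()
        assert abs(total) <= 1e-8 * max(scale, 1e-300)

    def test_pressure_decays_away_from_source(self):
        """A single strongly leaky segment acts as a pressure source; P_i
        decreases monotonically with distance along a ray from it."""
        from conftest import capillary_island_network
        net = capillary_island_network()
        net.Lp[:] = 1.0e-2
        params = FlowParams()
        node_P = np.full(net.n_nodes, 30.0)
        P, _ = solve_interstitial_pressure(net, params, node_P)
        ray = P[4:, 4, 4]
        assert np.all(np.diff(ray) < 0)


class TestPicardCoupling:
    def test_decoupled_limit_single_pass(self):
        net = line_network(6, Lp=0.0)
        flow = picard_couple_flow(net, FlowParams())
        assert flow.picard_iterations == 1
        assert np.all(flow.P_i == 0.0)

    def test_mass_residual_small(self, baseline_flow_30):
        net, params, flow = baseline_flow_30
        assert flow.mass_residual < 1e-8

    def test_relaxation_reaches_same_fixed_point(self):
        net = line_network(6, radius=5.0, Lp=1.0e-3)
        p1 = FlowParams(relax=1.0)
        p2 = FlowParams(relax=0.5)
        f1 = picard_couple_flow(net, p1)
        f2 = picard_couple_flow(net.copy(), p2)
        assert np.allclose(f1.node_P, f2.node_P, atol=1e-5)
        assert np.allclose(f1.P_i, f2.P_i, atol=1e-5)


class TestRheology:
    def test_invivo_viscosity_frozen_values(self):
        """Hand-evaluated values of the empirical in-vivo viscosity law."""
        assert relative_viscosity_invivo(10.0, 0.45) == \
            pytest.approx(5.872437674178899, rel=1e-12)
        assert relative_viscosity_invivo(30.0, 0.45) == \
            pytest.approx(2.5219868438153497, rel=1e-12)

    def test_plasma_limit_at_zero_haematocrit(self):
        """H = 0 leaves only the diameter-dependent plasma factor (≈ 1)."""
        D = 10.0
        w2 = (D / (D - 1.1)) ** 4
        assert relative_viscosity_invivo(D, 0.0) == pytest.approx(
            np.sqrt(w2), rel=1e-12)
        assert viscosity(5.0, 0.0, 1.0) == pytest.approx(
            relative_viscosity_invivo(10.0, 0.0))

    def test_monotone_in_haematocrit(self):
        H = np.linspace(0.0, 0.8, 30)
        mu = relative_viscosity_invivo(10.0, H)
        assert np.all(np.diff(mu) > 0)


class TestPhaseSeparation:
    def test_symmetric_split_equal_haematocrit(self):
        h1, h2 = phase_separation(0.45, 100.0, 10.0, 50.0, 8.0, 50.0, 8.0)
        assert h1 == pytest.approx(h2)
        assert h1 == pytest.approx(0.45, rel=1e-12)

    @pytest.mark.parametrize("split", [0.2, 0.35, 0.5, 0.65, 0.8])
    def test_rbc_flux_conserved(self, split):
        Qp, Hp = 120.0, 0.4
        h1, h2 = phase_separation(Hp, Qp, 12.0, split * Qp, 8.0,
                                  (1 - split) * Qp, 8.0)
        assert h1 * split * Qp + h2 * (1 - split) * Qp == \
            pytest.approx(Hp * Qp, rel=1e-12)

    def test_high_flow_branch_gets_disproportionate_rbc_share(self):
        """Logit law: at a 70/30 flow split the high-flow daughter receives
        ~79% of the RBC flux (hand-evaluated)."""
        Qp, Hp = 100.0, 0.45
        h1, _ = phase_separation(Hp, Qp, 10.0, 70.0, 8.0, 30.0, 8.0)
        fqe1 = h1 * 70.0 / (Hp * Qp)
        assert fqe1 == pytest.approx(0.7912880186830612, rel=1e-9)
        assert fqe1 > 0.70

    def test_zero_parent_flow_inherits(self):
        assert phase_separation(0.3, 0.0, 10.0, 0.0, 8.0, 0.0, 8.0) \
            == (0.3, 0.3)


class TestWallShearStress:
    def test_formula_and_linearity(self):
        net = line_network(2, radius=5.0, Lp=0.0)
        node_P = np.array([15.0, 16.0, 18.0])
        tau = wall_shear_stress(net, node_P)
        dl = net.grid.spacing
        # segments are (1,0) and (2,1): |ΔP|·R/(2Δl)
        assert tau[0] == pytest.approx(1.0 * 5.0 / (2 * dl))
        assert tau[1] == pytest.approx(2.0 * 5.0 / (2 * dl))
        net.radius[0] *= 2
        assert wall_shear_stress(net, node_P)[0] == pytest.approx(
            2 * tau[0])

    def test_zero_pressure_drop_and_collapsed(self):
        net = line_network(2, radius=5.0)
        tau = wall_shear_stress(net, np.full(net.n_nodes, 15.0))
        assert np.all(tau == 0.0)
        net.collapsed[0] = True
        tau = wall_shear_stress(net, np.array([15.0, 16.0, 17.0]))
        assert tau[0] == 0.0 and tau[1] > 0

    def test_f0_is_mean_over_order3(self, baseline_flow_30):
        net, params, flow = baseline_flow_30
        from oxynet.config import ORDER_ART3
        mask = (net.order == ORDER_ART3) & net.active
        assert flow.f0 == pytest.approx(flow.tau[mask].mean())


class TestNetworkConservation:
    def test_node_flow_residuals(self, baseline_flow_30):
        net, params, flow = baseline_flow_30
        assert node_flow_residuals(net, flow).max() < 1e-6

    def test_rbc_flux_conserved_at_nodes(self, baseline_flow_30):
        """Σ H·Q entering = Σ H·Q leaving at every internal junction."""
        net, params, flow = baseline_flow_30
        absQ = np.abs(flow.Qv)
        qmax = absQ[net.active].max()
        src = np.where(flow.Qv >= 0, net.seg_nodes[:, 0], net.seg_nodes[:, 1])
        dst = np.where(flow.Qv >= 0, net.seg_nodes[:, 1], net.seg_nodes[:, 0])
        rbc_in = np.zeros(net.n_nodes)
        rbc_out = np.zeros(net.n_nodes)
        q_in = np.zeros(net.n_nodes)
        q_out = np.zeros(net.n_nodes)
        act = np.flatnonzero(net.active & (absQ > 1e-12 * qmax))
        np.add.at(rbc_in, dst[act], absQ[act] * flow.H[act])
        np.add.at(rbc_out, src[act], absQ[act] * flow.H[act])
        np.add.at(q_in, dst[act], absQ[act])
        np.add.at(q_out, src[act], absQ[act])
        # transvascular plasma leak thins the blood flow at each node; the
        # discharge-haematocrit bookkeeping carries that leak, so RBC flux
        # is conserved up to each node's share of the adjacent leaks
        leak_node = np.zeros(net.n_nodes)
        np.add.at(leak_node, net.seg_nodes[act, 0], 0.5 * np.abs(flow.Qt[act]))
        np.add.at(leak_node, net.seg_nodes[act, 1], 0.5 * np.abs(flow.Qt[act]))
        interior = (net.node_tag == 0) & (q_in > 0) & (q_out > 0)
        err = np.abs(rbc_in[interior] - rbc_out[interior])
        allowed = leak_node[interior] + 1e-8 * np.maximum(rbc_in[interior],
                                                          1e-300)
        assert np.all(err <= allowed)
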