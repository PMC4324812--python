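"""Oxygen transport and ECM/MDE oracles: Hill equilibrium, advection,
transvascular exchange, diffusion-consumption, steady-state solve."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxynet import hb_equilibrium, hill_saturation, solve_chemicals_to_steady
from oxynet.chemicals import (ChemicalFields, advect_intravascular_o2,
                              diffuse_consume_tissue, implicit_diffusion,
                              invert_total_o2, solve_intravascular_steady,
                              step_ecm_mde, total_o2, transvascular_o2_flux,
                              wall_transfer_velocity)
from oxynet.config import ChemicalParams, FlowParams, GridSpec
from oxynet.hemodynamics import FlowState, picard_couple_flow
from oxynet.network import set_baseline_permeability

from conftest import capillary_island_network, line_network, make_network


def _flow_for(net, params=None):
    params = params or FlowParams()
    return picard_couple_flow(net, params)


def _manual_flow(net, node_P, Qv, H=0.45):
    M = net.n_segments
    return FlowState(
        node_P=np.asarray(node_P, float),
        Qv=np.asarray(Qv, float),
        Qt=np.zeros(M), U_v=np.zeros(M),
        H=np.full(M, H), mu=np.zeros(M), tau=np.zeros(M),
        P_i=np.zeros(net.grid.shape),
        U_i=np.zeros(net.grid.shape + (3,)))


class TestHbEquilibrium:
    def test_hill_midpoint_is_half(self, chem_params):
        assert hill_saturation(chem_params.c50, chem_params) == 0.5

    def test_bound_at_midpoint(self, chem_params):
        c = chem_params.c50
        assert hb_equilibrium(c, 0.4, chem_params) == pytest.approx(
            2 * 0.4 * chem_params.C_Hb)

    def test_zero_haematocrit_zero_bound(self, chem_params):
        assert hb_equilibrium(1e-13, 0.0, chem_params) == 0.0

    def test_saturation_monotone_and_bounded(self, chem_params):
        c = np.linspace(0, 20 * chem_params.c50, 200)
        s = hill_saturation(c, chem_params)
        assert np.all(np.diff(s) > 0)
        assert np.all(s < 1.0) and s[0] == 0.0

    @given(st.floats(min_value=1e-16, max_value=1e-12),
           st.floats(min_value=0.0, max_value=0.9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invert_total_roundtrip(self, c, H):
        params = ChemicalParams()
        tot = float(total_o2(c, H, params))
        back = invert_total_o2(tot, H, params)
        assert back == pytest.approx(c, rel=1e-8)


class TestEcmMde:
    def _empty_net(self):
        net = make_network(GridSpec(8, 8, 8), [(0, 0, 0)], {}, [])
        return net

    def test_mde_exponential_decay(self, chem_params):
        """Uniform MDE with no production decays as e^{-λt} (decay is
        integrated exactly; diffusion of a uniform field is a no-op)."""
        net = self._empty_net()
        fields = ChemicalFields.zeros(net.grid, 0)
        fields.C_m[:] = 3.0e-12
        t = 5400.0
        step_ecm_mde(fields, np.zeros(net.grid.shape), net, chem_params, t)
        expected = 3.0e-12 * np.exp(-chem_params.lambda_mde * t)
        assert np.allclose(fields.C_m, expected, rtol=1e-12)

    def test_ecm_unchanged_without_mde(self, chem_params):
        net = self._empty_net()
        fields = ChemicalFields.zeros(net.grid, 0)
        before = fields.C_f.copy()
        step_ecm_mde(fields, np.zeros(net.grid.shape), net, chem_params,
                     5400.0)
        assert np.array_equal(fields.C_f, before)

    def test_ecm_monotone_nonincreasing(self, chem_params):
        net = self._empty_net()
        fields = ChemicalFields.zeros(net.grid, 0)
        prod = np.zeros(net.grid.shape)
        prod[4, 4, 4] = chem_params.mu_T
        prev = fields.C_f.copy()
        for _ in range(5):
            step_ecm_mde(fields, prod, net, chem_params, 5400.0)
            assert np.all(fields.C_f <= prev + 1e-15)
            prev = fields.C_f.copy()
        assert fields.C_f[4, 4, 4] < 1.0

    def test_mde_mass_conservation_without_decay(self):
        """λ = 0, no-flux boundaries: total MDE mass equals production
        rate × time (implicit diffusion conserves the discrete sum)."""
        params = ChemicalParams(lambda_mde=0.0)
        net = self._empty_net()
        fields = ChemicalFields.zeros(net.grid, 0)
        prod = np.zeros(net.grid.shape)
        prod[2, 3, 4] = params.mu_T
        dt, n = 1000.0, 4
        for _ in range(n):
            step_ecm_mde(fields, prod, net, params, dt)
        total = fields.C_m.sum() * net.grid.voxel_volume
        assert total == pytest.approx(params.mu_T * dt * n, rel=1e-10)


class TestAdvection:
    def test_zero_velocity_unchanged(self, chem_params):
        net = line_network(5)
        flow = _manual_flow(net, np.full(net.n_nodes, 15.0),
                            np.zeros(net.n_segments))
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        fields.seg_CoF[:] = 5e-14
        before = fields.seg_CoF.copy()
        advect_intravascular_o2(net, flow, fields, chem_params, 1.0)
        assert np.array_equal(fields.seg_CoF, before)

    def test_steady_single_vessel_reaches_inlet_concentration(self,
                                                              chem_params):
        net = line_network(5)
        node_P = np.linspace(15.0, 18.5, net.n_nodes)  # node 0 is outlet
        Qv = np.full(net.n_segments, 800.0)  # a -> b i.e. inlet -> outlet
        flow = _manual_flow(net, node_P, Qv)
        flow.U_v = Qv / (np.pi * net.radius ** 2)
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        for _ in range(200):
            advect_intravascular_o2(net, flow, fields, chem_params, 5.0)
        assert np.allclose(fields.seg_CoF, chem_params.C_O2_inlet,
                           rtol=1e-6)

    def test_converging_node_mixes_flow_weighted(self, chem_params):
        """Two equal parents carrying c1 and c2 merge into (c1+c2)/2."""
        grid = GridSpec(7, 5, 4, 10.0)
        nodes = [(2, 3, 1), (4, 3, 1), (3, 3, 1), (3, 2, 1), (3, 1, 1)]
        from oxynet.network import TAG_INLET, TAG_OUTLET
        tags = {0: TAG_INLET, 1: TAG_INLET, 4: TAG_OUTLET}
        segs = [(0, 2), (1, 2), (2, 3), (3, 4)]
        net = make_network(grid, nodes, tags, segs, radius=4.0)
        node_P = np.array([18.5, 18.5, 17.0, 16.0, 15.0])
        Qv = np.array([500.0, 500.0, 1000.0, 1000.0])
        flow = _manual_flow(net, node_P, Qv, H=0.0)
        flow.U_v = Qv / (np.pi * net.radius ** 2)
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        c1, c2 = 2e-14, 6e-14
        fields.seg_CoF[:] = [c1, c2, 0.0, 0.0]
        # one sub-CFL step: downstream segment picks up the mixed value
        advect_intravascular_o2(net, flow, fields, chem_params,
                                grid.spacing / flow.U_v.max())
        assert fields.seg_CoF[2] == pytest.approx((c1 + c2) / 2, rel=1e-9)


class TestTransvascularExchange:
    def test_equal_concentrations_no_flux(self, chem_params):
        net = capillary_island_network()
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        fields.seg_CoF[:] = 4e-14
        fields.C_o[:] = 4e-14
        h = np.full(net.n_segments, 5.0)
        moved = transvascular_o2_flux(net, fields, chem_params, h, 5.0)
        assert moved == pytest.approx(0.0, abs=1e-30)

    def test_exchange_conserves_total_mass(self, chem_params):
        net = capillary_island_network()
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        rng = np.random.default_rng(0)
        fields.seg_CoF[:] = 1.2e-13
        fields.C_o[:] = rng.uniform(0, 1e-13, net.grid.shape)
        V_seg = np.pi * net.radius[0] ** 2 * net.grid.spacing
        V_vox = net.grid.voxel_volume
        before = fields.seg_CoF.sum() * V_seg + fields.C_o.sum() * V_vox
        h = np.full(net.n_segments, 50.0)
        transvascular_o2_flux(net, fields, chem_params, h, 5.0)
        after = fields.seg_CoF.sum() * V_seg + fields.C_o.sum() * V_vox
        assert after == pytest.approx(before, rel=1e-14)

    def test_two_box_relaxation_matches_ode(self, chem_params):
        """Closed two-compartment exchange relaxes as e^{-kt} with
        k = h·A·(1/V1 + 1/V2); compared against the analytic solution."""
        net = capillary_island_network(radius=4.0)
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        c_v0, c_t0 = 1.0e-13, 2.0e-14
        fields.seg_CoF[:] = c_v0
        fields.C_o[:] = c_t0
        h_val = 2.0
        h = np.full(net.n_segments, h_val)
        dt, n_steps = 0.05, 40
        for _ in range(n_steps):
            transvascular_o2_flux(net, fields, chem_params, h, dt)
        # analytic: the segment exchanges with its two endpoint voxels
        # (half the wall area each); by symmetry both voxels track each
        # other, so the system is a two-box ODE with A = 2πRΔl and the
        # tissue pool 2·V_vox
        R, dl = net.radius[0], net.grid.spacing
        A = 2 * np.pi * R * dl
        V1 = np.pi * R ** 2 * dl
        V2 = 2 * net.grid.voxel_volume
        k = h_val * A * (1 / V1 + 1 / V2)
        t = dt * n_steps
        c_eq = (V1 * c_v0 + V2 * c_t0) / (V1 + V2)
        expected_v = c_eq + (c_v0 - c_eq) * np.exp(-k * t)
        assert fields.seg_CoF[0] == pytest.approx(expected_v, rel=1e-4)


class TestTissueDiffusionConsumption:
    def test_uniform_field_no_cells_unchanged(self, chem_params):
        fields = ChemicalFields.zeros(GridSpec(8, 8, 8), 0)
        fields.C_o[:] = 7e-14
        consumed = diffuse_consume_tissue(fields, np.zeros((8, 8, 8)),
                                          chem_params, 5.0, 10.0)
        assert consumed == 0.0
        assert np.allclose(fields.C_o, 7e-14, rtol=1e-12)

    def test_consumption_only_closed_form(self, chem_params):
        """With D = 0 a consuming voxel drains linearly and floors at 0."""
        params = ChemicalParams(D_o=0.0)
        grid = GridSpec(4, 4, 4, 10.0)
        fields = ChemicalFields.zeros(grid, 0)
        c0 = 1.0e-13
        fields.C_o[:] = c0
        rate = np.zeros(grid.shape)
        rate[1, 1, 1] = chem_params.gamma
        dt = 0.5
        per_step = chem_params.gamma * dt / grid.voxel_volume
        for n in range(1, 4):
            diffuse_consume_tissue(fields, rate, params, dt, grid.spacing)
            assert fields.C_o[1, 1, 1] == pytest.approx(
                max(0.0, c0 - n * per_step), abs=1e-20)
        for _ in range(20):
            diffuse_consume_tissue(fields, rate, params, dt, grid.spacing)
        assert fields.C_o[1, 1, 1] == 0.0

    def test_implicit_diffusion_conserves_mass_and_smooths(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 1, (12, 12, 12))
        out = implicit_diffusion(C, 1000.0, 5.0, 10.0)
        assert out.sum() == pytest.approx(C.sum(), rel=1e-12)
        assert out.max() <= C.max() + 1e-12
        assert out.min() >= C.min() - 1e-12


class TestSteadyState:
    def test_no_vessels_no_cells_zero_steady(self, chem_params):
        net = make_network(GridSpec(6, 6, 6), [(0, 0, 0)], {}, [])
        fields = ChemicalFields.zeros(net.grid, 0)
        flow = _manual_flow(net, np.zeros(1), np.zeros(0))
        res = solve_chemicals_to_steady(net, flow, np.zeros(net.grid.shape),
                                        fields, chem_params,
                                        np.zeros(0))
        assert res.converged
        assert np.all(fields.C_o == 0.0)

    def test_steady_state_independent_of_initial_guess(self):
        """Two solves started from dry and saturated tissue agree."""
        params = ChemicalParams(tol_chem=1e-8)
        fp = FlowParams()
        net = line_network(n_segments=8, radius=5.0, Lp=fp.Lp_normal)
        flow = _flow_for(net, fp)
        h = wall_transfer_velocity(net.Lp, fp.Lp_normal, params)
        cons = np.zeros(net.grid.shape)
        cons[2, 4, 2] = params.gamma     # one consuming voxel near vessel
        finals = []
        for c0 in (0.0, params.C_O2_inlet):
            fields = ChemicalFields.zeros(net.grid, net.n_segments)
            fields.C_o[:] = c0
            solve_chemicals_to_steady(net, flow, cons, fields, params, h,
                                      max_iter=20000)
            finals.append(fields.C_o.copy())
        scale = finals[1].max()
        assert np.abs(finals[0] - finals[1]).max() / scale < 1e-5

    def test_oxygen_decays_with_distance_from_single_vessel(self,
                                                            chem_params):
        """One perfused vessel in uniformly consuming tissue: the steady
        O2 field decreases monotonically with lattice distance."""
        fp = FlowParams()
        net = line_network(n_segments=8, radius=5.0, pad=6, Lp=fp.Lp_normal)
        flow = _flow_for(net, fp)
        params = ChemicalParams(tol_chem=1e-7)
        h = wall_transfer_velocity(net.Lp, fp.Lp_normal, params)
        cons = np.full(net.grid.shape, 0.25 * params.gamma)
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        fields.C_o[:] = params.C_O2_inlet
        solve_chemicals_to_steady(net, flow, cons, fields, params, h,
                                  max_iter=20000)
        mid = fields.C_o[:, 4, 6]     # ray away from the vessel at x=6...
        ray = fields.C_o[6:, 4, 6]
        assert np.all(np.diff(ray) <= 1e-18)

    def test_delivery_equals_consumption_at_steady(self):
        """Closed steady-state balance on a small vascularised domain."""
        params = ChemicalParams(tol_chem=1e-10, sweep_every=1)
        fp = FlowParams()
        net = line_network(n_segments=8, radius=5.0, pad=4, Lp=fp.Lp_normal)
        flow = _flow_for(net, fp)
        h = wall_transfer_velocity(net.Lp, fp.Lp_normal, params)
        cons = np.zeros(net.grid.shape)
        cons[3:6, 3:6, 3:6] = 0.5 * params.gamma
        fields = ChemicalFields.zeros(net.grid, net.n_segments)
        fields.C_o[:] = params.C_O2_inlet
        res = solve_chemicals_to_steady(net, flow, cons, fields, params, h,
                                        max_iter=50000)
        assert res.converged
        assert res.balance_error < 1e-6
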