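"""Coupled intravascular, transvascular and interstitial haemodynamics.

Intravascular flow is Poiseuille flow on the segment graph with flux
conservation at every node; leakage across the wall follows Starling's law
and couples the network to a Darcy interstitium, whose pressure obeys a
screened Poisson equation with sources in vessel-containing voxels.  Blood
rheology uses the Pries–Secomb in-vivo viscosity law and the logit
phase-separation law for red-blood-cell partitioning at bifurcations.

Units: µm, s, mmHg (see :mod:`oxynet.units`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .config import FlowParams, GridSpec, ORDER_ART3
from .network import TAG_INLET, TAG_OUTLET, VascularNetwork

#: haematocrit ceiling used when clamping phase-separation output
H_MAX = 0.95

#: flows below this fraction of the network maximum are treated as stagnant
Q_STAGNANT_FRAC = 1.0e-12


class FlowSolverError(RuntimeError):
    """Raised when a haemodynamic solve fails to converge."""


# ---------------------------------------------------------------------------
# rheology
# ---------------------------------------------------------------------------

def relative_viscosity_invivo(D: float | np.ndarray,
                              H: float | np.ndarray) -> np.ndarray:
    """Pries–Secomb in-vivo relative apparent viscosity.

    Parameters
    ----------
    D : vessel diameter, µm
    H : discharge haematocrit in [0, 1]

    Returns the apparent viscosity relative to plasma.  Inputs are clamped
    to their physical ranges.
    """
    D = np.maximum(np.asarray(D, dtype=float), 3.0)
    H = np.clip(np.asarray(H, dtype=float), 0.0, 0.99)
    mu45 = 6.0 * np.exp(-0.085 * D) + 3.2 - 2.44 * np.exp(-0.06 * D ** 0.645)
    d12 = 1.0 / (1.0 + 1.0e-11 * D ** 12)
    C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + d12) + d12
    W = (D / (D - 1.1)) ** 2
    frac = ((1.0 - H) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    return (1.0 + (mu45 - 1.0) * frac * W) * W


def viscosity(R: float | np.ndarray, H: float | np.ndarray,
              mu_plasma: float) -> np.ndarray:
    """Effective blood viscosity of a segment of radius ``R`` (µm), mmHg·s."""
    return mu_plasma * relative_viscosity_invivo(2.0 * np.asarray(R), H)


def phase_separation(H_parent: float, Q_parent: float, D_parent: float,
                     Q_d1: float, D_d1: float,
                     Q_d2: float, D_d2: float) -> tuple[float, float]:
    """RBC partitioning at a diverging bifurcation (Pries–Secomb logit law).

    Returns the discharge haematocrits of the two daughters.  RBC flux is
    conserved: ``H_parent*Q_parent == H1*Q_d1 + H2*Q_d2`` (up to the
    clamping of daughter haematocrit at :data:`H_MAX`, where the excess is
    returned to the other branch).
    """
    if Q_parent <= 0.0:
        return H_parent, H_parent
    fqb1 = Q_d1 / Q_parent
    x0 = 0.964 * (1.0 - H_parent) / D_parent
    if fqb1 <= x0:
        fqe1 = 0.0
    elif fqb1 >= 1.0 - x0:
        fqe1 = 1.0
    else:
        A = -13.29 * ((D_d1 ** 2 - D_d2 ** 2) / (D_d1 ** 2 + D_d2 ** 2)) \
            * (1.0 - H_parent) / D_parent
        B = 1.0 + 6.98 * (1.0 - H_parent) / D_parent
        x = (fqb1 - x0) / (1.0 - 2.0 * x0)
        logit = A + B * math.log(x / (1.0 - x))
        fqe1 = 1.0 / (1.0 + math.exp(-logit))
    rbc_flux = H_parent * Q_parent
    h1 = fqe1 * rbc_flux / Q_d1 if Q_d1 > 0 else H_parent
    h2 = (1.0 - fqe1) * rbc_flux / Q_d2 if Q_d2 > 0 else H_parent
    # clamp with flux-conserving hand-back
    if h1 > H_MAX and Q_d2 > 0:
        h2 += (h1 - H_MAX) * Q_d1 / Q_d2
        h1 = H_MAX
    if h2 > H_MAX and Q_d1 > 0:
        h1 += (h2 - H_MAX) * Q_d2 / Q_d1
        h2 = H_MAX
    return min(h1, 1.0), min(h2, 1.0)


# ---------------------------------------------------------------------------
# state container
# ---------------------------------------------------------------------------

@dataclass
class FlowState:
    """Converged haemodynamic state of a network."""

    node_P: np.ndarray        #: per-node intravascular pressure, mmHg
    Qv: np.ndarray            #: per-segment vascular flow a→b (signed), µm³/s
    Qt: np.ndarray            #: per-segment transvascular leak rate, µm³/s
    U_v: np.ndarray           #: per-segment mean velocity (signed), µm/s
    H: np.ndarray             #: per-segment discharge haematocrit
    mu: np.ndarray            #: per-segment effective viscosity, mmHg·s
    tau: np.ndarray           #: per-segment wall shear stress, mmHg
    P_i: np.ndarray           #: interstitial pressure field (3D), mmHg
    U_i: np.ndarray           #: interstitial velocity field (3D, 3), µm/s
    f0: float = np.nan        #: baseline mean WSS of order-3 arterioles, mmHg
    picard_iterations: int = 0
    mass_residual: float = np.nan  #: relative global mass-balance error

    @property
    def Q(self) -> np.ndarray:
        """Net segment flow Q = Q_v − Q_t."""
        return self.Qv - self.Qt

    def inflow_outflow(self, net: VascularNetwork) -> tuple[float, float]:
        """Net flow entering at the inlet plane and leaving at the outlet."""
        n = net.n_nodes
        out_of_node = np.zeros(n)   # signed flow leaving each node
        act = np.flatnonzero(net.active)
        a = net.seg_nodes[act, 0]
        b = net.seg_nodes[act, 1]
        np.add.at(out_of_node, a, self.Qv[act])
        np.add.at(out_of_node, b, -self.Qv[act])
        # each segment's leak is shared half-and-half between its endpoints;
        # a boundary node's share is drawn from the feeding vasculature
        np.add.at(out_of_node, a, 0.5 * self.Qt[act])
        np.add.at(out_of_node, b, 0.5 * self.Qt[act])
        inflow = float(out_of_node[net.node_tag == TAG_INLET].sum())
        outflow = float(-out_of_node[net.node_tag == TAG_OUTLET].sum())
        return inflow, outflow


# ---------------------------------------------------------------------------
# voxel-wise vessel source maps
# ---------------------------------------------------------------------------

def vessel_voxel_sources(net: VascularNetwork, node_P: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (flat) masks and averages used by the interstitial solve.

    Returns ``(vox_idx, Lp_vox, Pv_vox)`` over voxels touched by at least
    one active segment; each segment contributes half its weight to each
    endpoint voxel.
    """
    act = np.flatnonzero(net.active)
    if len(act) == 0:
        return (np.empty(0, np.int64), np.empty(0), np.empty(0))
    endpoints = net.segment_midpoint_voxels()[act]          # (m, 2)
    vox = endpoints.ravel()
    w = np.repeat(0.5, 2 * len(act))
    Lp_w = np.repeat(net.Lp[act], 2) * w
    Pv_seg = 0.5 * (node_P[net.seg_nodes[act, 0]] +
                    node_P[net.seg_nodes[act, 1]])
    Pv_w = np.repeat(Pv_seg, 2) * w
    n_vox = net.grid.n_voxels
    w_sum = np.bincount(vox, weights=w, minlength=n_vox)
    Lp_sum = np.bincount(vox, weights=Lp_w, minlength=n_vox)
    Pv_sum = np.bincount(vox, weights=Pv_w, minlength=n_vox)
    idx = np.flatnonzero(w_sum > 0)
    return idx, Lp_sum[idx] / w_sum[idx], Pv_sum[idx] / w_sum[idx]


# ---------------------------------------------------------------------------
# network (intravascular) solve
# ---------------------------------------------------------------------------

def _segment_leak_conductance(net: VascularNetwork) -> np.ndarray:
    """2πRΔl·L_p per segment (zero where collapsed)."""
    c = 2.0 * np.pi * net.radius * net.grid.spacing * net.Lp
    c[~net.active] = 0.0
    return c


def solve_network_flow(net: VascularNetwork, params: FlowParams,
                       P_i: np.ndarray, mu_seg: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve node pressures with Poiseuille conductances and Starling leak.

    Parameters
    ----------
    P_i : 3D interstitial pressure field (mmHg)
    mu_seg : per-segment effective viscosity (mmHg·s)

    Returns ``(node_P, Qv, Qt)``.  Components of the active graph that do
    not reach any Dirichlet (inlet/outlet) node are dropped from the solve
    and assigned zero flow.
    """
    n = net.n_nodes
    dl = net.grid.spacing
    act = np.flatnonzero(net.active)
    node_P = np.full(n, params.P_outlet)

    if len(act) == 0:
        return node_P, np.zeros(net.n_segments), np.zeros(net.n_segments)

    a = net.seg_nodes[act, 0]
    b = net.seg_nodes[act, 1]
    g = np.pi * net.radius[act] ** 4 / (8.0 * mu_seg[act] * dl)
    c_leak = _segment_leak_conductance(net)[act]

    P_i_flat = np.asarray(P_i).reshape(-1)
    vox_ab = net.segment_midpoint_voxels()[act]
    Pi_mid = 0.5 * (P_i_flat[vox_ab[:, 0]] + P_i_flat[vox_ab[:, 1]])
    Pi_eff = Pi_mid + params.osmotic_term   # Starling balance point

    # connected components reaching a boundary node
    adj = sp.coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    has_bc = np.zeros(n_comp, bool)
    bc_nodes = np.flatnonzero((net.node_tag == TAG_INLET) |
                              (net.node_tag == TAG_OUTLET))
    has_bc[np.unique(labels[bc_nodes])] = True
    solvable_seg = has_bc[labels[a]]

    dirichlet = np.zeros(n, bool)
    dirichlet[net.node_tag == TAG_INLET] = True
    dirichlet[net.node_tag == TAG_OUTLET] = True
    P_bc = np.where(net.node_tag == TAG_INLET,
                    params.P_outlet + params.delta_P_drive, params.P_outlet)

    in_solve = has_bc[labels] & ~dirichlet
    # nodes only touched by unsolvable components keep the reference pressure
    free_idx = np.flatnonzero(in_solve)
    if len(free_idx):
        remap = -np.ones(n, np.int64)
        remap[free_idx] = np.arange(len(free_idx))

        rows, cols, vals = [], [], []
        rhs = np.zeros(len(free_idx))

        sa, sb = a[solvable_seg], b[solvable_seg]
        sg = g[solvable_seg]
        sc = c_leak[solvable_seg]
        spi = Pi_eff[solvable_seg]

        def add(i, j, v):
            rows.append(i); cols.append(j); vals.append(v)

        for ai, bi, gi, ci, pii in zip(sa, sb, sg, sc, spi):
            fa, fb = remap[ai], remap[bi]
            # node a row
            if fa >= 0:
                add(fa, fa, gi + ci / 4.0)
                rhs[fa] += ci / 2.0 * pii
                if fb >= 0:
                    add(fa, fb, -gi + ci / 4.0)
                else:
                    rhs[fa] -= (-gi + ci / 4.0) * P_bc[bi]
            if fb >= 0:
                add(fb, fb, gi + ci / 4.0)
                rhs[fb] += ci / 2.0 * pii
                if fa >= 0:
                    add(fb, fa, -gi + ci / 4.0)
                else:
                    rhs[fb] -= (-gi + ci / 4.0) * P_bc[ai]

        A = sp.coo_matrix((vals, (rows, cols)),
                          shape=(len(free_idx), len(free_idx))).tocsr()
        try:
            sol = spla.spsolve(A, rhs)
        except RuntimeError as exc:  # pragma: no cover - singular fallback
            raise FlowSolverError(f"network flow solve failed: {exc}")
        node_P[free_idx] = sol

    node_P[dirichlet] = P_bc[dirichlet]

    Qv = np.zeros(net.n_segments)
    Qt = np.zeros(net.n_segments)
    Qv[act[solvable_seg]] = g[solvable_seg] * (node_P[a[solvable_seg]] -
                                               node_P[b[solvable_seg]])
    Pbar = 0.5 * (node_P[a] + node_P[b])
    Qt_act = c_leak * (Pbar - Pi_eff)
    Qt_act[~solvable_seg] = 0.0
    Qt[act] = Qt_act
    return node_P, Qv, Qt


# ---------------------------------------------------------------------------
# interstitial (Darcy) solve
# ---------------------------------------------------------------------------

_LAPLACIAN_CACHE: dict[tuple, sp.csr_matrix] = {}


def _neumann_laplacian(shape: tuple[int, int, int], spacing: float
                       ) -> sp.csr_matrix:
    """Positive-semidefinite 7-point −∇² with no-flux boundaries, 1/µm²."""
    key = (shape, spacing)
    L = _LAPLACIAN_CACHE.get(key)
    if L is None:
        def lap1d(m: int) -> sp.csr_matrix:
            main = np.full(m, 2.0)
            main[0] = main[-1] = 1.0
            off = np.full(m - 1, -1.0)
            return sp.diags([off, main, off], [-1, 0, 1], format="csr")

        Ls = [lap1d(m) for m in shape]
        eye = [sp.identity(m, format="csr") for m in shape]
        L = (sp.kron(sp.kron(Ls[0], eye[1]), eye[2]) +
             sp.kron(sp.kron(eye[0], Ls[1]), eye[2]) +
             sp.kron(sp.kron(eye[0], eye[1]), Ls[2])).tocsr()
        L = L / spacing ** 2
        _LAPLACIAN_CACHE[key] = L
    return L


def solve_interstitial_pressure(net: VascularNetwork, params: FlowParams,
                                node_P: np.ndarray,
                                P_i_init: np.ndarray | None = None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Solve −K∇²P_i = L_p(S/V)(P_v − P_i − σ_T Δπ) with no-flux boundaries.

    The source acts only in vessel-containing voxels.  Returns the pressure
    field and the Darcy velocity ``U_i = −K ∇P_i`` (central differences).
    With no vessels present the field is the zero-mean constant (zeros).
    """
    grid = net.grid
    shape = grid.shape
    vox_idx, Lp_vox, Pv_vox = vessel_voxel_sources(net, node_P)

    if len(vox_idx) == 0 or np.all(Lp_vox == 0.0):
        P = np.zeros(shape)
        return P, np.zeros(shape + (3,))

    beta = np.zeros(grid.n_voxels)
    beta[vox_idx] = Lp_vox * params.S_over_V
    rhs = np.zeros(grid.n_voxels)
    rhs[vox_idx] = beta[vox_idx] * (Pv_vox - params.osmotic_term)

    L = _neumann_laplacian(shape, grid.spacing)
    A = (params.K * L + sp.diags(beta)).tocsr()
    M = sp.diags(1.0 / A.diagonal())
    x0 = None if P_i_init is None else np.asarray(P_i_init).reshape(-1)
    sol, info = spla.cg(A, rhs, x0=x0, rtol=params.tol_interstitial,
                        atol=0.0, maxiter=20000, M=M)
    if info != 0:
        resid = np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
        raise FlowSolverError(
            f"interstitial pressure CG did not converge (info={info}, "
            f"relative residual {resid:.3e})")
    P = sol.reshape(shape)
    grads = np.gradient(P, grid.spacing, edge_order=1)
    U_i = -params.K * np.stack(grads, axis=-1)
    return P, U_i


# ---------------------------------------------------------------------------
# haematocrit sweep
# ---------------------------------------------------------------------------

def haematocrit_sweep(net: VascularNetwork, node_P: np.ndarray,
                      Qv: np.ndarray, params: FlowParams,
                      H_prev: np.ndarray | None = None) -> np.ndarray:
    """Propagate discharge haematocrit through the network in flow order.

    Nodes are processed in order of decreasing pressure (flow is acyclic in
    a pressure-driven network).  At diverging bifurcations with two
    daughters the Pries–Secomb phase-separation law partitions the RBC
    flux; with three or more daughters each inherits the mixed value.
    Stagnant segments keep their previous haematocrit.
    """
    M = net.n_segments
    H = (np.full(M, params.H_inlet) if H_prev is None else H_prev.copy())
    act = np.flatnonzero(net.active)
    if len(act) == 0:
        return H
    q_floor = Q_STAGNANT_FRAC * max(np.abs(Qv[act]).max(), 1e-300)

    # directed incidence: flow travels from the higher- to lower-pressure node
    a = net.seg_nodes[:, 0]
    b = net.seg_nodes[:, 1]
    src = np.where(Qv >= 0, a, b)
    dst = np.where(Qv >= 0, b, a)

    out_segs: list[list[int]] = [[] for _ in range(net.n_nodes)]
    in_segs: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for s in act:
        if abs(Qv[s]) <= q_floor:
            continue
        out_segs[src[s]].append(s)
        in_segs[dst[s]].append(s)

    order = np.argsort(-node_P, kind="stable")
    absQ = np.abs(Qv)
    D = 2.0 * net.radius
    for node in order:
        outs = out_segs[node]
        if not outs:
            continue
        ins = in_segs[node]
        if ins:
            q_in = sum(absQ[s] for s in ins)
            rbc_in = sum(absQ[s] * H[s] for s in ins)
            h_mix = rbc_in / q_in if q_in > 0 else params.H_inlet
            d_parent = sum(absQ[s] * D[s] for s in ins) / q_in
        else:
            h_mix = params.H_inlet      # inlet-plane (root) nodes
            d_parent = max(D[s] for s in outs)
            q_in = sum(absQ[s] for s in outs)
        if len(outs) == 1:
            H[outs[0]] = h_mix
        elif len(outs) == 2:
            s1, s2 = outs
            h1, h2 = phase_separation(h_mix, q_in, d_parent,
                                      absQ[s1], D[s1], absQ[s2], D[s2])
            # renormalise to the actual outgoing flux (q_out may differ
            # from q_in by the transvascular leak)
            H[s1], H[s2] = h1, h2
        else:
            for s in outs:
                H[s] = h_mix
    return np.clip(H, 0.0, 1.0)


# ---------------------------------------------------------------------------
# wall shear stress
# ---------------------------------------------------------------------------

def wall_shear_stress(net: VascularNetwork, node_P: np.ndarray) -> np.ndarray:
    """τ = |ΔP_v|·R/(2Δl) per segment; zero for collapsed segments."""
    dP = np.abs(node_P[net.seg_nodes[:, 0]] - node_P[net.seg_nodes[:, 1]])
    tau = dP * net.radius / (2.0 * net.grid.spacing)
    tau[~net.active] = 0.0
    return tau


def baseline_wss_reference(net: VascularNetwork, tau: np.ndarray) -> float:
    """f0: mean WSS of the order-3 arteriole segments (baseline network)."""
    mask = (net.order == ORDER_ART3) & net.active
    if not mask.any():
        return float("nan")
    return float(tau[mask].mean())


# ---------------------------------------------------------------------------
# Picard coupling
# ---------------------------------------------------------------------------

def picard_couple_flow(net: VascularNetwork, params: FlowParams,
                       P_i_init: np.ndarray | None = None,
                       H_init: np.ndarray | None = None,
                       f0: float | None = None) -> FlowState:
    """Alternate network and interstitial solves to the coupled fixed point.

    Within each outer (Picard) pass the viscosity–haematocrit subproblem is
    itself iterated to a fixed point.  Convergence is declared when the
    maximum change of both P_v and P_i falls below ``params.tol_couple``.
    """
    grid = net.grid
    P_i = np.zeros(grid.shape) if P_i_init is None else P_i_init.copy()
    H = (np.full(net.n_segments, params.H_inlet)
         if H_init is None else H_init.copy())
    node_P_old = None
    c_leak_total = _segment_leak_conductance(net).sum()
    decoupled = (c_leak_total == 0.0) or np.isnan(c_leak_total)

    node_P = Qv = Qt = None
    n_outer = 0
    for n_outer in range(1, params.max_picard_iter + 1):
        # viscosity / haematocrit inner fixed point
        for _ in range(8):
            mu = viscosity(net.radius, H, params.mu_plasma)
            node_P, Qv, Qt = solve_network_flow(net, params, P_i, mu)
            H_new = haematocrit_sweep(net, node_P, Qv, params, H_prev=H)
            dH = np.max(np.abs(H_new - H)) if len(H) else 0.0
            H = H_new
            if dH < 1.0e-8:
                break
        if decoupled:
            P_i_new = P_i
        else:
            P_i_new, _ = solve_interstitial_pressure(net, params, node_P,
                                                     P_i_init=P_i)
        dPi = np.max(np.abs(P_i_new - P_i))
        P_i = P_i + params.relax * (P_i_new - P_i)
        dPv = (np.inf if node_P_old is None
               else np.max(np.abs(node_P - node_P_old)))
        node_P_old = node_P.copy()
        # tolerance relative to the pressure scale of the problem
        p_scale = max(float(np.abs(node_P).max()), 1.0)
        if decoupled or max(dPi, dPv) < params.tol_couple * p_scale:
            break
    else:
        raise FlowSolverError(
            f"Picard flow coupling did not converge in "
            f"{params.max_picard_iter} iterations "
            f"(try a smaller relaxation factor, relax < {params.relax})")

    if decoupled:
        U_i = np.zeros(grid.shape + (3,))
        P_i_field = np.zeros(grid.shape)
    else:
        P_i_field, U_i = solve_interstitial_pressure(net, params, node_P,
                                                     P_i_init=P_i)

    area = np.pi * np.maximum(net.radius, 1e-30) ** 2
    U_v = np.where(net.active, Qv / area, 0.0)
    tau = wall_shear_stress(net, node_P)
    state = FlowState(node_P=node_P, Qv=Qv, Qt=Qt, U_v=U_v, H=H,
                      mu=viscosity(net.radius, H, params.mu_plasma),
                      tau=tau, P_i=P_i_field, U_i=U_i,
                      picard_iterations=n_outer)
    state.f0 = baseline_wss_reference(net, tau) if f0 is None else f0
    state.mass_residual = global_mass_residual(net, state)
    return state


def global_mass_residual(net: VascularNetwork, flow: FlowState) -> float:
    """Relative error of (inlet inflow) − (outlet outflow) − Σ Q_t."""
    inflow, outflow = flow.inflow_outflow(net)
    leak = float(flow.Qt[net.active].sum())
    scale = max(abs(inflow), abs(outflow), 1e-300)
    return abs(inflow - outflow - leak) / scale


def node_flow_residuals(net: VascularNetwork, flow: FlowState) -> np.ndarray:
    """Per-interior-node |ΣQ| normalised by the largest segment flow."""
    n = net.n_nodes
    net_in = np.zeros(n)
    act = np.flatnonzero(net.active)
    a = net.seg_nodes[act, 0]
    b = net.seg_nodes[act, 1]
    np.add.at(net_in, b, flow.Qv[act])
    np.add.at(net_in, a, -flow.Qv[act])
    # subtract each segment's leak, half per endpoint
    np.add.at(net_in, a, -0.5 * flow.Qt[act])
    np.add.at(net_in, b, -0.5 * flow.Qt[act])
    interior = net.node_tag == 0
    scale = max(np.abs(flow.Qv[act]).max(initial=0.0), 1e-300)
    return np.abs(net_in[interior]) / scale
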