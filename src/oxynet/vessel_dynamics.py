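"""Vessel cooption, compliance remodelling, and collapse.

A pre-existing segment touched by active tumour cells becomes *immature*:
it dilates at a fixed rate up to a maximum radius while its wall hydraulic
permeability rises toward the tumour-tissue value, L_p = L_p^T·R/R_max.
Immature segments respond to the transmural pressure through the empirical
compliance law R = R0·((P_v − P_i + P_c)/E)^b and collapse outright if the
base becomes non-positive.  Independently, a vessel fully surrounded by
tumour collapses stochastically after sustained low wall shear stress
(τ < τ_crit = 0.5·f0), with probability growing linearly with the low-WSS
duration.  Collapse is absorbing: a collapsed segment never rejoins the
flow graph.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .cells import CellGrid, N, P, Q
from .config import VesselDynParams
from .hemodynamics import FlowState
from .network import VascularNetwork

__all__ = ["coopt_and_dilate", "remodel_radius", "wss_collapse",
           "segments_touching_active_tumour", "segments_surrounded_by_tumour"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _segment_endpoint_mask_values(net: VascularNetwork,
                                  field: np.ndarray) -> np.ndarray:
    """(M, 2) boolean field values at each segment's endpoint voxels."""
    flat = field.reshape(-1)
    return flat[net.segment_midpoint_voxels()]


def segments_touching_active_tumour(net: VascularNetwork,
                                    cells: CellGrid) -> np.ndarray:
    """Cooption trigger: at least one active (P or Q) tumour cell in or
    face-adjacent to an endpoint voxel of the segment."""
    active_tc = (cells.phenotype == P) | (cells.phenotype == Q)
    near = ndimage.binary_dilation(active_tc, structure=_STRUCT6)
    return _segment_endpoint_mask_values(net, near).any(axis=1)


def segments_surrounded_by_tumour(net: VascularNetwork,
                                  cells: CellGrid) -> np.ndarray:
    """Collapse eligibility: every face-adjacent tissue voxel of both
    endpoint voxels is occupied by tumour (any phenotype).

    Vessel-containing voxels themselves are not required to hold a cell;
    the predicate asks that the segment be embedded in tumour tissue.
    """
    occupied = (cells.phenotype != 0)
    vessel_vox = np.zeros(net.grid.n_voxels, bool)
    act = net.active
    if act.any():
        vessel_vox[net.segment_midpoint_voxels()[act].ravel()] = True
    vessel_vox = vessel_vox.reshape(net.grid.shape)
    # a voxel is "embedded" if all its 6-neighbours are tumour or vessel
    free = ~(occupied | vessel_vox)
    # neighbour count of non-tumour, non-vessel voxels
    has_free_neighbour = ndimage.binary_dilation(free, structure=_STRUCT6)
    embedded = ~has_free_neighbour
    return _segment_endpoint_mask_values(net, embedded).all(axis=1)


def coopt_and_dilate(net: VascularNetwork, cells: CellGrid,
                     params: VesselDynParams, dt_hours: float) -> np.ndarray:
    """Mark tumour-contacted segments immature and dilate them (in place).

    Immature segments grow ``dilation_rate × dt_hours`` in radius while
    ``R <= R_max`` (capped at R_max); their wall permeability follows
    L_p = L_p^T·(1 − (R_max − R)/R_max), and R0 tracks the dilated radius
    so the compliance law acts on the coopted calibre.  Returns the mask of
    newly coopted segments.
    """
    touched = segments_touching_active_tumour(net, cells) & net.active
    newly = touched & net.mature
    net.mature[newly] = False

    immature = ~net.mature & net.active
    if immature.any():
        R = net.radius[immature]
        R = np.minimum(R + params.dilation_rate * dt_hours, params.R_max)
        net.radius[immature] = R
        net.radius0[immature] = R
        net.Lp[immature] = params.Lp_tumour * R / params.R_max
    return newly


def remodel_radius(net: VascularNetwork, flow: FlowState,
                   params: VesselDynParams) -> np.ndarray:
    """Compliance remodelling of immature segments (in place).

    R = R0·((P_v − P_i + P_c)/E)^b with segment-mean P_v and the
    interstitial pressure at the segment midpoint; mature segments keep R0.
    A non-positive base collapses the segment immediately (compression).
    Returns the mask of compression-collapsed segments.
    """
    immature = ~net.mature & net.active
    collapsed_now = np.zeros(net.n_segments, bool)
    if not immature.any():
        return collapsed_now
    idx = np.flatnonzero(immature)
    Pv = 0.5 * (flow.node_P[net.seg_nodes[idx, 0]] +
                flow.node_P[net.seg_nodes[idx, 1]])
    Pi_flat = flow.P_i.reshape(-1)
    eps = net.segment_midpoint_voxels()[idx]
    Pi = 0.5 * (Pi_flat[eps[:, 0]] + Pi_flat[eps[:, 1]])
    base = (Pv - Pi + params.P_c) / params.E
    crushed = base <= 0.0
    net.radius[idx[~crushed]] = (net.radius0[idx[~crushed]]
                                 * base[~crushed] ** params.b)
    if crushed.any():
        collapse_segments(net, idx[crushed])
        collapsed_now[idx[crushed]] = True
    return collapsed_now


def wss_collapse(net: VascularNetwork, flow: FlowState, cells: CellGrid,
                 params: VesselDynParams, rng: np.random.Generator,
                 f0: float) -> np.ndarray:
    """Stochastic collapse of tumour-surrounded, chronically low-WSS
    segments (in place).

    For eligible segments with τ < tau_crit_frac·f0 the low-WSS duration
    counter advances and the segment collapses with probability
    min(1, p_collapse_unit × duration); the counter resets once τ
    recovers.  Returns the mask of segments collapsed this call.
    """
    collapsed_now = np.zeros(net.n_segments, bool)
    if not np.isfinite(f0):
        return collapsed_now
    tau_crit = params.tau_crit_frac * f0
    surrounded = segments_surrounded_by_tumour(net, cells)
    low = net.active & surrounded & (flow.tau < tau_crit)
    net.low_wss_duration[net.active & ~low] = 0
    idx = np.flatnonzero(low)
    if len(idx) == 0:
        return collapsed_now
    net.low_wss_duration[idx] += 1
    p = np.minimum(1.0, params.p_collapse_unit * net.low_wss_duration[idx])
    draws = rng.random(len(idx))
    doomed = idx[draws < p]
    if len(doomed):
        collapse_segments(net, doomed)
        collapsed_now[doomed] = True
    return collapsed_now


def collapse_segments(net: VascularNetwork, idx: np.ndarray) -> None:
    """Permanently remove segments from the flow graph."""
    net.collapsed[idx] = True
    net.radius[idx] = 0.0
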