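"""Shared fixtures: hand-built micro-networks and reusable simulation runs."""
from __future__ import annotations

import numpy as np
import pytest

from oxynet.config import (ChemicalParams, FlowParams, GridSpec, SimConfig,
                           ORDER_ART3, ORDER_CAP)
from oxynet.network import (TAG_INLET, TAG_INTERIOR, TAG_OUTLET,
                            VascularNetwork, set_baseline_permeability)


def make_network(grid: GridSpec, nodes: list[tuple[int, int, int]],
                 tags: dict[int, int],
                 segments: list[tuple[int, int]],
                 radius: float | list[float] = 5.0,
                 order: int = ORDER_ART3) -> VascularNetwork:
    """Assemble a VascularNetwork from explicit nodes and lattice-edge
    segments (test scaffolding)."""
    n_seg = len(segments)
    radii = (np.full(n_seg, radius) if np.isscalar(radius)
             else np.asarray(radius, float))
    node_tag = np.full(len(nodes), TAG_INTERIOR, np.int8)
    for idx, tag in tags.items():
        node_tag[idx] = tag
    net = VascularNetwork(
        grid=grid,
        node_ijk=np.asarray(nodes, np.int32),
        node_tag=node_tag,
        seg_nodes=(np.asarray(segments, np.int32).reshape(n_seg, 2)
                   if n_seg else np.empty((0, 2), np.int32)),
        radius=radii.copy(),
        radius0=radii.copy(),
        order=np.full(n_seg, order, np.int8),
        mature=np.ones(n_seg, bool),
        Lp=np.zeros(n_seg),
        wall_thickness=np.ones(n_seg),
        collapsed=np.zeros(n_seg, bool),
        low_wss_duration=np.zeros(n_seg, np.int32),
    )
    return net


def line_network(n_segments: int = 8, radius: float = 5.0,
                 pad: int = 2, Lp: float = 0.0) -> VascularNetwork:
    """A single straight vessel along y; inlet at y = max, outlet at y = 0."""
    ny = n_segments + 1 + 2 * pad
    size = max(2 * pad + 1, 4)
    grid = GridSpec(size, max(ny, 4), size, 10.0)
    cx = cz = pad
    nodes = [(cx, j, cz) for j in range(n_segments + 1)]
    tags = {0: TAG_OUTLET, n_segments: TAG_INLET}
    segs = [(j + 1, j) for j in range(n_segments)]   # a = upstream (higher y)
    net = make_network(grid, nodes, tags, segs, radius=radius)
    net.Lp[:] = Lp
    return net


def y_bifurcation_network(radius_parent: float = 8.0,
                          radius_daughter: float = 5.0) -> VascularNetwork:
    """Symmetric Y: parent from the inlet plane splits into two equal
    daughters that both reach the outlet plane."""
    grid = GridSpec(9, 6, 4, 10.0)
    nodes = [
        (4, 5, 1), (4, 4, 1), (4, 3, 1),          # parent chain (inlet j=5)
        (3, 3, 1), (5, 3, 1),                      # lateral junction arms
        (3, 2, 1), (3, 1, 1), (3, 0, 1),           # left daughter to outlet
        (5, 2, 1), (5, 1, 1), (5, 0, 1),           # right daughter to outlet
    ]
    tags = {0: TAG_INLET, 7: TAG_OUTLET, 10: TAG_OUTLET}
    segments = [(0, 1), (1, 2),
                (2, 3), (2, 4),
                (3, 5), (5, 6), (6, 7),
                (4, 8), (8, 9), (9, 10)]
    radii = [radius_parent, radius_parent,
             radius_daughter, radius_daughter,
             radius_daughter, radius_daughter, radius_daughter,
             radius_daughter, radius_daughter, radius_daughter]
    return make_network(grid, nodes, tags, segments, radius=radii)


def capillary_island_network(radius: float = 4.0) -> VascularNetwork:
    """One capillary segment in the middle of a small grid (no boundary
    connection; used for cooption/dilation micro-experiments)."""
    grid = GridSpec(9, 9, 9, 10.0)
    nodes = [(4, 4, 4), (4, 5, 4)]
    net = make_network(grid, nodes, {}, [(1, 0)], radius=radius,
                       order=ORDER_CAP)
    return net


def _reduced_config(n: int = 30, steps: int = 6, *, mvd: float = 1.0,
                    seed: int = 1, oxygen_mode: str = "flow_dependent",
                    cooption: bool = True, remodelling: bool = True,
                    collapse: bool = True, tol_chem: float = 1.0e-5,
                    sweep_every: int = 4, n_seed_cells: int = 20
                    ) -> SimConfig:
    d = SimConfig().to_dict()
    d["grid"].update(n_x=n, n_y=n, n_z=n)
    d["network"]["mvd_multiplier"] = mvd
    d["chem"].update(tol_chem=tol_chem, sweep_every=sweep_every)
    d["cells"]["n_seed_cells"] = n_seed_cells
    d.update(n_steps=steps, oxygen_mode=oxygen_mode,
             enable_cooption=cooption, enable_remodelling=remodelling,
             enable_collapse=collapse,
             seed_network=seed, seed_cells=seed + 100,
             seed_collapse=seed + 200)
    return SimConfig.from_dict(d)


@pytest.fixture(scope="session")
def reduced_config():
    return _reduced_config


@pytest.fixture(scope="session")
def baseline_flow_30():
    """Coupled haemodynamic solve on the default 30³ network (session-wide)."""
    from oxynet import build_network, picard_couple_flow
    grid = GridSpec(30, 30, 30)
    net = build_network(grid, seed=1)
    params = FlowParams()
    set_baseline_permeability(net, params.Lp_normal)
    flow = picard_couple_flow(net, params)
    return net, params, flow


@pytest.fixture(scope="session")
def mvd_suite():
    """MVD-sensitivity study: 0.5×/1.0×/1.5× networks, three seeds each,
    eight steps on a 30³ grid.  Returns {(case, seed): summaries}."""
    from oxynet import run_simulation
    out = {}
    for case, mvd in (("a", 0.5), ("b", 1.0), ("c", 1.5)):
        for seed in (1, 2, 3):
            cfg = _reduced_config(n=30, steps=8, mvd=mvd, seed=seed)
            out[(case, seed)] = run_simulation(cfg).summaries
    return out


@pytest.fixture(scope="session")
def static_network_run():
    """Baseline run with all vessel dynamics disabled (static network)."""
    from oxynet import run_simulation
    cfg = _reduced_config(n=30, steps=6, cooption=False, remodelling=False,
                          collapse=False)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def chem_params():
    return ChemicalParams()
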