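"""Procedural generation of the pre-existing 3D arteriolar network.

The synthetic vasculature emulates a regular arteriolar bed in a 1 mm³ tissue
cube: parallel arterioles run the full y-extent of the lattice, laid out on a
regular (x, z) raster with 100 µm spacing at baseline density, and
cross-linking capillaries bridge adjacent arterioles at random heights.
Three arteriole calibres (diameters 50/30/10 µm, proportions 10%/20%/70%)
give the bed its heterogeneity; capillaries have 8 µm diameter.

Segments live on lattice edges (length = one lattice constant).  The network
is stored column-oriented in numpy arrays; node i of the lattice coincides
with the centre of voxel (i, j, k).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .config import (ARTERIOLE_DIAMETERS_UM, ARTERIOLE_PROPORTIONS,
                     CAPILLARY_DIAMETER_UM, ConfigError, GridSpec,
                     NetworkParams, ORDER_ART1, ORDER_ART3, ORDER_CAP,
                     ORDER_NAMES)

#: node boundary tags
TAG_INTERIOR, TAG_INLET, TAG_OUTLET = 0, 1, 2


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed."""


@dataclass
class VascularNetwork:
    """Graph of lattice nodes and unit-length vessel segments."""

    grid: GridSpec
    node_ijk: np.ndarray          #: (N, 3) int lattice coordinates
    node_tag: np.ndarray          #: (N,) int8, TAG_* codes
    seg_nodes: np.ndarray         #: (M, 2) int node indices
    radius: np.ndarray            #: (M,) current radius R, µm
    radius0: np.ndarray           #: (M,) origin radius R0, µm
    order: np.ndarray             #: (M,) int8 order codes (1,2,3 art.; 4 cap.)
    mature: np.ndarray            #: (M,) bool
    Lp: np.ndarray                #: (M,) hydraulic wall permeability, µm/(mmHg·s)
    wall_thickness: np.ndarray    #: (M,) µm
    collapsed: np.ndarray         #: (M,) bool
    low_wss_duration: np.ndarray  #: (M,) int32 consecutive low-WSS steps
    seed: int = 0
    arteriole_id: np.ndarray = field(default=None)  #: (M,) int, -1 for capillaries

    def __post_init__(self) -> None:
        if self.arteriole_id is None:
            self.arteriole_id = np.full(self.n_segments, -1, dtype=np.int32)

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ijk)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    @property
    def active(self) -> np.ndarray:
        """Mask of segments participating in the flow graph."""
        return ~self.collapsed

    @property
    def node_voxel(self) -> np.ndarray:
        """Flat voxel index of each node."""
        return np.ravel_multi_index(self.node_ijk.T, self.grid.shape)

    def segment_length(self) -> float:
        """Length of every segment (all segments are one lattice edge)."""
        return self.grid.spacing

    def total_length(self, active_only: bool = True) -> float:
        mask = self.active if active_only else np.ones(self.n_segments, bool)
        return float(mask.sum()) * self.grid.spacing

    def segment_midpoint_voxels(self) -> np.ndarray:
        """(M, 2) voxel indices of the two endpoints of each segment.

        Transvascular exchange is split evenly between the two endpoint
        voxels (the midpoint of a lattice edge lies on their shared face).
        """
        vox = self.node_voxel
        return vox[self.seg_nodes]

    def counts_by_order(self, active_only: bool = True) -> dict[str, int]:
        mask = self.active if active_only else np.ones(self.n_segments, bool)
        return {ORDER_NAMES[o]: int(np.sum(self.order[mask] == o))
                for o in sorted(ORDER_NAMES)}

    def is_connected_inlet_to_outlet(self) -> bool:
        """Graph-search check that some inlet node reaches some outlet node
        through non-collapsed segments."""
        act = self.active
        if not act.any():
            return False
        a, b = self.seg_nodes[act, 0], self.seg_nodes[act, 1]
        n = self.n_nodes
        adj = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
        inlet_labels = set(labels[self.node_tag == TAG_INLET])
        outlet_labels = set(labels[self.node_tag == TAG_OUTLET])
        return bool(inlet_labels & outlet_labels)

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            grid=self.grid,
            node_ijk=self.node_ijk.copy(),
            node_tag=self.node_tag.copy(),
            seg_nodes=self.seg_nodes.copy(),
            radius=self.radius.copy(),
            radius0=self.radius0.copy(),
            order=self.order.copy(),
            mature=self.mature.copy(),
            Lp=self.Lp.copy(),
            wall_thickness=self.wall_thickness.copy(),
            collapsed=self.collapsed.copy(),
            low_wss_duration=self.low_wss_duration.copy(),
            seed=self.seed,
            arteriole_id=self.arteriole_id.copy(),
        )


# ---------------------------------------------------------------------------
# order assignment
# ---------------------------------------------------------------------------

def assign_orders(n_arterioles: int,
                  proportions: tuple[float, ...] = ARTERIOLE_PROPORTIONS,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Assign calibre orders 1..len(proportions) to arterioles.

    Counts follow the target proportions by the largest-remainder rule,
    which reproduces the proportions exactly whenever ``n × p`` is integral.
    The mapping of counts onto individual arterioles is a random permutation
    when ``rng`` is given, else deterministic in index order.
    """
    p = np.asarray(proportions, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ConfigError("order proportions must sum to 1")
    ideal = n_arterioles * p
    counts = np.floor(ideal).astype(int)
    remainder = n_arterioles - counts.sum()
    if remainder > 0:
        # ties broken toward the lower order index (stable argsort)
        frac_rank = np.argsort(-(ideal - counts), kind="stable")
        counts[frac_rank[:remainder]] += 1
    labels = np.repeat(np.arange(1, len(p) + 1, dtype=np.int8), counts)
    if rng is not None:
        labels = rng.permutation(labels)
    return labels


def _line_positions(n_sites: int, spacing: int, multiplier: float) -> np.ndarray:
    """Evenly spaced lattice positions of arteriole lines along one axis.

    At multiplier 1.0 this is exactly every ``spacing``-th coordinate from 0;
    other multipliers scale the count linearly and spread the lines evenly
    over the same extent.
    """
    base = int(np.ceil(n_sites / spacing))
    n = max(1, round(base * multiplier))
    if n == 1:
        return np.array([(n_sites - spacing) // 2], dtype=int)
    pos = np.round(np.linspace(0, n_sites - spacing, n)).astype(int)
    return np.unique(pos)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

def build_network(grid: GridSpec,
                  params: NetworkParams | None = None,
                  seed: int = 0,
                  *,
                  mvd_multiplier: float | None = None,
                  capillary_link_prob: float | None = None) -> VascularNetwork:
    """Generate the pre-existing network on ``grid``.

    Arterioles are parallel lines spanning the full y-extent, one per
    (x, z) raster position; the inlet plane is y = max, the outlet plane
    y = 0.  Capillary bridges (straight lattice paths between adjacent
    arteriole lines) are drawn stochastically.  Deterministic for a fixed
    ``seed``.
    """
    params = params or NetworkParams()
    if mvd_multiplier is not None or capillary_link_prob is not None:
        params = NetworkParams(
            line_spacing=params.line_spacing,
            mvd_multiplier=(params.mvd_multiplier if mvd_multiplier is None
                            else mvd_multiplier),
            capillary_link_prob=(params.capillary_link_prob
                                 if capillary_link_prob is None
                                 else capillary_link_prob),
            wall_thickness=params.wall_thickness,
        )
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid.shape
    sp = params.line_spacing

    xs = _line_positions(nx, sp, params.mvd_multiplier)
    zs = _line_positions(nz, sp, 1.0)
    lines = list(itertools.product(xs, zs))
    if len(lines) < 2:
        raise ConfigError(
            f"grid {grid.shape} too small to place at least 2 arterioles")

    orders = assign_orders(len(lines), rng=rng)

    node_index: dict[tuple[int, int, int], int] = {}
    node_list: list[tuple[int, int, int]] = []

    def get_node(i: int, j: int, k: int) -> int:
        key = (i, j, k)
        idx = node_index.get(key)
        if idx is None:
            idx = len(node_list)
            node_index[key] = idx
            node_list.append(key)
        return idx

    seg_a: list[int] = []
    seg_b: list[int] = []
    seg_order: list[int] = []
    seg_art: list[int] = []

    # arterioles: full-length lines along y
    for art_id, ((x, z), order) in enumerate(zip(lines, orders)):
        prev = get_node(x, 0, z)
        for j in range(1, ny):
            cur = get_node(x, j, z)
            seg_a.append(prev)
            seg_b.append(cur)
            seg_order.append(int(order))
            seg_art.append(art_id)
            prev = cur

    # capillaries: straight bridges between adjacent lines (same z, adjacent
    # x — and same x, adjacent z), one Bernoulli trial per pair per
    # line-spacing-wide window along y
    n_windows = max(1, ny // sp)
    existing_edges = set()

    def add_capillary_path(p0: tuple[int, int, int],
                           p1: tuple[int, int, int]) -> None:
        """Straight lattice path between two nodes differing in one axis."""
        (i0, j0, k0), (i1, j1, k1) = p0, p1
        axis = 0 if i0 != i1 else 2
        lo, hi = (i0, i1) if axis == 0 else (k0, k1)
        step = 1 if hi > lo else -1
        prev = get_node(i0, j0, k0)
        for c in range(lo + step, hi + step, step):
            nxt = (get_node(c, j0, k0) if axis == 0 else get_node(i0, j0, c))
            edge = (min(prev, nxt), max(prev, nxt))
            if edge not in existing_edges:
                existing_edges.add(edge)
                seg_a.append(prev)
                seg_b.append(nxt)
                seg_order.append(ORDER_CAP)
                seg_art.append(-1)
            prev = nxt

    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for zi in zs:
        for xa, xb in zip(xs[:-1], xs[1:]):
            pairs.append(((xa, zi), (xb, zi)))
    for xi in xs:
        for za, zb in zip(zs[:-1], zs[1:]):
            pairs.append(((xi, za), (xi, zb)))

    for (xa, za), (xb, zb) in pairs:
        for w in range(n_windows):
            if rng.random() < params.capillary_link_prob:
                j_lo = w * sp
                j_hi = min(ny, (w + 1) * sp)
                j = int(rng.integers(j_lo, j_hi))
                add_capillary_path((xa, j, za), (xb, j, zb))

    node_ijk = np.asarray(node_list, dtype=np.int32)
    node_tag = np.full(len(node_list), TAG_INTERIOR, dtype=np.int8)
    # boundary tags only on arteriole ends (capillary bridges are interior)
    on_line = np.zeros(len(node_list), bool)
    line_set = set(lines)
    for idx, (i, j, k) in enumerate(node_list):
        if (i, k) in line_set:
            on_line[idx] = True
    node_tag[on_line & (node_ijk[:, 1] == ny - 1)] = TAG_INLET
    node_tag[on_line & (node_ijk[:, 1] == 0)] = TAG_OUTLET

    order_arr = np.asarray(seg_order, dtype=np.int8)
    radius = np.empty(len(order_arr))
    for o, d in ARTERIOLE_DIAMETERS_UM.items():
        radius[order_arr == o] = d / 2.0
    radius[order_arr == ORDER_CAP] = CAPILLARY_DIAMETER_UM / 2.0

    n_seg = len(order_arr)
    return VascularNetwork(
        grid=grid,
        node_ijk=node_ijk,
        node_tag=node_tag,
        seg_nodes=np.column_stack([seg_a, seg_b]).astype(np.int32),
        radius=radius,
        radius0=radius.copy(),
        order=order_arr,
        mature=np.ones(n_seg, bool),
        Lp=np.full(n_seg, np.nan),  # filled below
        wall_thickness=np.full(n_seg, params.wall_thickness),
        collapsed=np.zeros(n_seg, bool),
        low_wss_duration=np.zeros(n_seg, np.int32),
        seed=seed,
        arteriole_id=np.asarray(seg_art, dtype=np.int32),
    )


def set_baseline_permeability(net: VascularNetwork, Lp_normal: float) -> None:
    """Initialise all (mature) segments to the normal-tissue permeability."""
    net.Lp[:] = Lp_normal


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["id", "node_a", "node_b", "radius_um", "radius0_um", "order",
                "maturity", "Lp", "wall_thickness_um", "collapsed",
                "low_wss_duration", "arteriole_id"]


def write_network(net: VascularNetwork, directory: str | Path) -> None:
    """Write ``nodes.csv`` and ``segments.csv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame({
        "id": np.arange(net.n_nodes),
        "i": net.node_ijk[:, 0],
        "j": net.node_ijk[:, 1],
        "k": net.node_ijk[:, 2],
        "boundary_tag": net.node_tag,
    })
    segs = pd.DataFrame({
        "id": np.arange(net.n_segments),
        "node_a": net.seg_nodes[:, 0],
        "node_b": net.seg_nodes[:, 1],
        "radius_um": net.radius,
        "radius0_um": net.radius0,
        "order": net.order,
        "maturity": np.where(net.mature, "mature", "immature"),
        "Lp": net.Lp,
        "wall_thickness_um": net.wall_thickness,
        "collapsed": net.collapsed.astype(int),
        "low_wss_duration": net.low_wss_duration,
        "arteriole_id": net.arteriole_id,
    })
    meta = pd.DataFrame({
        "n_x": [net.grid.n_x], "n_y": [net.grid.n_y], "n_z": [net.grid.n_z],
        "spacing_um": [net.grid.spacing], "seed": [net.seed],
    })
    nodes.to_csv(directory / "nodes.csv", index=False)
    segs.to_csv(directory / "segments.csv", index=False)
    meta.to_csv(directory / "grid.csv", index=False)


def read_network(directory: str | Path) -> VascularNetwork:
    """Read a network written by :func:`write_network` (lossless)."""
    directory = Path(directory)
    try:
        meta = pd.read_csv(directory / "grid.csv")
        nodes = pd.read_csv(directory / "nodes.csv")
        segs = pd.read_csv(directory / "segments.csv")
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise NetworkFormatError(f"cannot read network from {directory}: {exc}")
    for col in ("n_x", "n_y", "n_z", "spacing_um", "seed"):
        if col not in meta.columns:
            raise NetworkFormatError(f"grid.csv missing column {col!r}")
    for col in ("id", "i", "j", "k", "boundary_tag"):
        if col not in nodes.columns:
            raise NetworkFormatError(f"nodes.csv missing column {col!r}")
    for col in _SEG_COLUMNS:
        if len(segs) and col not in segs.columns:
            raise NetworkFormatError(
                f"segments.csv missing required column {col!r}")
    grid = GridSpec(int(meta.n_x[0]), int(meta.n_y[0]), int(meta.n_z[0]),
                    float(meta.spacing_um[0]))
    n_seg = len(segs)
    return VascularNetwork(
        grid=grid,
        node_ijk=nodes[["i", "j", "k"]].to_numpy(np.int32),
        node_tag=nodes["boundary_tag"].to_numpy(np.int8),
        seg_nodes=(segs[["node_a", "node_b"]].to_numpy(np.int32)
                   if n_seg else np.empty((0, 2), np.int32)),
        radius=segs["radius_um"].to_numpy(float),
        radius0=segs["radius0_um"].to_numpy(float),
        order=segs["order"].to_numpy(np.int8),
        mature=(segs["maturity"] == "mature").to_numpy(bool),
        Lp=segs["Lp"].to_numpy(float),
        wall_thickness=segs["wall_thickness_um"].to_numpy(float),
        collapsed=segs["collapsed"].to_numpy(bool),
        low_wss_duration=segs["low_wss_duration"].to_numpy(np.int32),
        seed=int(meta.seed[0]),
        arteriole_id=segs["arteriole_id"].to_numpy(np.int32),
    )
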