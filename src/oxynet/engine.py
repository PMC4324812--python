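"""Simulation engine: initialise, iterate, summarise, persist.

One outer step (1.5 h of model time) performs, in order: haemodynamic
solve → chemicals iterated to steady state → tumour-cell automaton update →
vessel cooption/dilation → compliance remodelling → WSS collapse.  Three
independent RNG streams (network construction, cell decisions, collapse
draws) make each stochastic source separately reproducible.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
import pandas as pd

from . import cells as cellmod
from . import chemicals as chem
from . import network as netmod
from . import vessel_dynamics as vd
from .config import ORDER_NAMES, SimConfig
from .hemodynamics import FlowState, picard_couple_flow

__all__ = ["SimResult", "run_simulation", "profile_c_o_star",
           "o2_supply_by_order", "write_snapshot", "read_snapshot"]


@dataclass
class SimResult:
    """End state and per-step summaries of a simulation run."""

    config: SimConfig
    net: netmod.VascularNetwork
    cells: cellmod.CellGrid
    fields: chem.ChemicalFields
    flow: FlowState
    f0: float
    summaries: pd.DataFrame
    events: pd.DataFrame
    output_dir: Path | None = None

    def summary_hash(self) -> str:
        """Deterministic digest of the step summaries (for replay checks)."""
        payload = self.summaries.to_csv(index=False, float_format="%.12g")
        return hashlib.sha256(payload.encode()).hexdigest()


def _step_summary(step: int, net: netmod.VascularNetwork,
                  cells_grid: cellmod.CellGrid,
                  fields: chem.ChemicalFields, flow: FlowState,
                  chem_res: chem.ChemSolveResult | None,
                  config: SimConfig) -> dict:
    census = cells_grid.counts()
    seg_counts = net.counts_by_order(active_only=True)
    c_star = fields.normalised_o2(config.chem)
    k_mid = net.grid.n_z // 2
    prof, plane_avg = profile_c_o_star(c_star, axis="x", plane=k_mid)
    row = {
        "step": step,
        **{f"cells_{k}": v for k, v in census.items()},
        **{f"segments_{k.replace('-', '')}": v for k, v in seg_counts.items()},
        "segments_immature": int((~net.mature & net.active).sum()),
        "segments_collapsed": int(net.collapsed.sum()),
        "c_star_plane_mean": plane_avg,
        "c_star_plane_p10": float(np.percentile(
            c_star[:, :, k_mid], 10.0)),
        "c_star_plane_p90": float(np.percentile(
            c_star[:, :, k_mid], 90.0)),
        "c_star_centre": float(
            prof[net.grid.n_x // 2]),
        "mass_residual": flow.mass_residual,
        "picard_iterations": flow.picard_iterations,
        "chem_iterations": 0 if chem_res is None else chem_res.n_iterations,
        "chem_residual": np.nan if chem_res is None else chem_res.residual,
        "delivered_total_umol": float(fields.delivered.sum()),
    }
    for o, name in ORDER_NAMES.items():
        row[f"delivered_{name.replace('-', '')}_umol"] = float(
            fields.delivered[net.order == o].sum())
    return row


def run_simulation(config: SimConfig,
                   observer: Callable[[str, int], None] | None = None,
                   ) -> SimResult:
    """Run the full coupled simulation described by ``config``.

    ``observer(event, step)`` — if given — is called at each stage
    ("flow", "chemicals", "cells", "dilate", "remodel", "collapse"),
    which instruments the step ordering.  Deterministic replay: identical
    config and seeds give byte-identical summaries.
    """
    grid = config.grid
    rng_cells = np.random.default_rng(config.seed_cells)
    rng_collapse = np.random.default_rng(config.seed_collapse)

    net = netmod.build_network(grid, config.network, seed=config.seed_network)
    netmod.set_baseline_permeability(net, config.flow.Lp_normal)
    cells_grid = cellmod.seed_tumour(grid, config.cells, rng_cells)
    fields = chem.ChemicalFields.zeros(grid, net.n_segments)
    if net.active.any():
        # starting guess for the quasi-steady oxygen solve: oxygenated
        # tissue (the steady state does not depend on the guess, but a
        # perfused domain equilibrates near the inlet level, so this cuts
        # the cold-start iteration count substantially)
        fields.C_o[:] = config.chem.C_O2_inlet

    # baseline (pre-existing network) flow state defines f0
    flow = picard_couple_flow(net, config.flow)
    f0 = flow.f0

    events: list[dict] = []
    rows = [_step_summary(0, net, cells_grid, fields, flow, None, config)]
    step_seconds = config.step_hours * 3600.0
    chem_res = None

    for step in range(1, config.n_steps + 1):
        if observer:
            observer("flow", step)
        flow = picard_couple_flow(net, config.flow, P_i_init=flow.P_i,
                                  H_init=flow.H, f0=f0)

        if observer:
            observer("chemicals", step)
        h_seg = chem.wall_transfer_velocity(net.Lp, config.flow.Lp_normal,
                                            config.chem)
        cons = cellmod.consumption_field(cells_grid, config.chem)
        chem_res = chem.solve_chemicals_to_steady(
            net, flow, cons, fields, config.chem, h_seg,
            point_source=(config.oxygen_mode == "point_source"))
        fields.delivered += chem_res.delivery_rate * step_seconds
        chem.step_ecm_mde(fields,
                          cellmod.mde_production_field(cells_grid,
                                                       config.chem),
                          net, config.chem, step_seconds)

        if observer:
            observer("cells", step)
        cellmod.update_cells(cells_grid, fields.normalised_o2(config.chem),
                             config.cells, rng_cells)

        if observer:
            observer("dilate", step)
        if config.enable_cooption:
            newly = vd.coopt_and_dilate(net, cells_grid, config.vessel,
                                        config.step_hours)
            for s in np.flatnonzero(newly):
                events.append({"step": step, "segment": int(s),
                               "event": "dilation_start",
                               "radius_um": float(net.radius[s])})

        if observer:
            observer("remodel", step)
        if config.enable_remodelling:
            crushed = vd.remodel_radius(net, flow, config.vessel)
            for s in np.flatnonzero(crushed):
                events.append({"step": step, "segment": int(s),
                               "event": "collapse_compression",
                               "radius_um": 0.0})

        if observer:
            observer("collapse", step)
        if config.enable_collapse:
            fell = vd.wss_collapse(net, flow, cells_grid, config.vessel,
                                   rng_collapse, f0)
            for s in np.flatnonzero(fell):
                events.append({"step": step, "segment": int(s),
                               "event": "collapse_wss", "radius_um": 0.0})

        rows.append(_step_summary(step, net, cells_grid, fields, flow,
                                  chem_res, config))

    result = SimResult(
        config=config, net=net, cells=cells_grid, fields=fields, flow=flow,
        f0=f0,
        summaries=pd.DataFrame(rows),
        events=pd.DataFrame(events,
                            columns=["step", "segment", "event",
                                     "radius_um"]),
    )
    if config.output_dir:
        result.output_dir = Path(config.output_dir)
        _write_run_outputs(result)
    return result


def _write_run_outputs(result: SimResult) -> None:
    out = result.output_dir
    out.mkdir(parents=True, exist_ok=True)
    result.summaries.to_csv(out / "summaries.csv", index=False)
    result.events.to_csv(out / "events.csv", index=False)
    result.config.to_yaml(out / "config.yaml")
    netmod.write_network(result.net, out / "network")
    write_snapshot(out / "final_state.h5", result)


# ---------------------------------------------------------------------------
# reporting statistics
# ---------------------------------------------------------------------------

def profile_c_o_star(o2_normalised: np.ndarray, axis: str = "x",
                     plane: int | None = None) -> tuple[np.ndarray, float]:
    """Integrated oxygen profile c_o*(x) on a fixed z-plane.

    Averages the normalised tissue O2 over y at each x of the plane
    ``z = plane`` (default: mid-plane).  Returns the 1D profile and the
    plane average.
    """
    if axis != "x":
        raise ValueError("only the x-axis profile is defined")
    nz = o2_normalised.shape[2]
    if plane is None:
        plane = nz // 2
    if not 0 <= plane < nz:
        raise ValueError(f"plane z={plane} outside grid (nz={nz})")
    sl = o2_normalised[:, :, plane]
    profile = sl.mean(axis=1)
    return profile, float(sl.mean())


def o2_supply_by_order(net: netmod.VascularNetwork,
                       delivered: np.ndarray,
                       mode: str = "flow_dependent") -> dict[str, float]:
    """Fraction of oxygen supplied per vessel class.

    ``flow_dependent``: shares of the cumulative per-segment delivered O2.
    ``point_source``: every non-collapsed segment contributes equally, so
    the shares reduce to segment-count fractions.  Fractions sum to 1; an
    all-zero total yields NaN shares (undefined supply).
    """
    shares: dict[str, float] = {}
    if mode == "point_source":
        weights = net.active.astype(float)
    else:
        # collapsed segments keep credit for O2 delivered before collapse
        weights = np.asarray(delivered, dtype=float)
    total = weights.sum()
    for o, name in ORDER_NAMES.items():
        w = weights[net.order == o].sum()
        shares[name] = float(w / total) if total > 0 else float("nan")
    return shares


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def write_snapshot(path: str | Path, result: SimResult) -> None:
    """HDF5 snapshot with /network, /fields and /cells groups."""
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(result.config.to_dict())
        f.attrs["f0"] = result.f0
        g = f.create_group("network")
        net = result.net
        g.create_dataset("node_ijk", data=net.node_ijk)
        g.create_dataset("node_tag", data=net.node_tag)
        g.create_dataset("seg_nodes", data=net.seg_nodes)
        for name in ("radius", "radius0", "order", "mature", "Lp",
                     "wall_thickness", "collapsed", "low_wss_duration",
                     "arteriole_id"):
            g.create_dataset(name, data=getattr(net, name))
        g = f.create_group("fields")
        for name in ("C_f", "C_m", "C_o", "seg_CoF", "seg_CoB", "delivered"):
            g.create_dataset(name, data=getattr(result.fields, name))
        g = f.create_group("cells")
        g.create_dataset("phenotype", data=result.cells.phenotype)
        g.create_dataset("age", data=result.cells.age)
        g.create_dataset("necrotic_duration",
                         data=result.cells.necrotic_duration)
        g.create_dataset("ever_occupied", data=result.cells.ever_occupied)


def read_snapshot(path: str | Path) -> dict:
    """Load a snapshot into plain arrays plus the embedded config dict."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        out["config"] = json.loads(f.attrs["config_json"])
        out["f0"] = float(f.attrs["f0"])
        for group in ("network", "fields", "cells"):
            out[group] = {k: np.asarray(v) for k, v in f[group].items()}
    return out
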