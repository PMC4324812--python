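"""Probabilistic cellular automaton of tumour cell phenotypes.

Each voxel holds at most one cell: proliferating (P), quiescent (Q) or
necrotic (N).  Behaviour is driven by the local normalised oxygen
concentration against two thresholds: below the survival threshold a cell
necroses; above the proliferation threshold and with a free von-Neumann
neighbour it divides with probability T_age/T_TC (older cells divide more
readily); otherwise it is quiescent.  Necrotic cells persist for a fixed
lifetime and are then cleared stochastically, freeing the voxel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CellParams, ChemicalParams, GridSpec

#: phenotype codes
EMPTY, P, Q, N = 0, 1, 2, 3

#: oxygen-consumption multiplier by phenotype (×γ)
O2_CONSUMPTION_FACTOR = {EMPTY: 0.0, P: 1.0, Q: 0.5, N: 0.25}
#: MDE-production multiplier by phenotype (×µ_T)
MDE_PRODUCTION_FACTOR = {EMPTY: 0.0, P: 1.0, Q: 0.2, N: 0.1}

_NEIGHBOUR_OFFSETS = np.array([
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
], dtype=np.int64)


@dataclass
class CellGrid:
    """Per-voxel phenotype with cell-age and necrotic-duration counters."""

    phenotype: np.ndarray          #: (nx, ny, nz) uint8 phenotype codes
    age: np.ndarray                #: int16, 1..T_TC on live cells, else 0
    necrotic_duration: np.ndarray  #: int16, steps since necrosis on N voxels
    ever_occupied: np.ndarray      #: bool, voxels ever holding a tumour cell

    @classmethod
    def empty(cls, grid: GridSpec) -> "CellGrid":
        shape = grid.shape
        return cls(phenotype=np.zeros(shape, np.uint8),
                   age=np.zeros(shape, np.int16),
                   necrotic_duration=np.zeros(shape, np.int16),
                   ever_occupied=np.zeros(shape, bool))

    # -- census -------------------------------------------------------------

    def counts(self) -> dict[str, int]:
        ph = self.phenotype
        return {"P": int(np.sum(ph == P)), "Q": int(np.sum(ph == Q)),
                "N": int(np.sum(ph == N)),
                "total": int(np.sum(ph != EMPTY)),
                "invasive_area": int(self.ever_occupied.sum())}

    def occupied_mask(self) -> np.ndarray:
        return self.phenotype != EMPTY

    def copy(self) -> "CellGrid":
        return CellGrid(self.phenotype.copy(), self.age.copy(),
                        self.necrotic_duration.copy(),
                        self.ever_occupied.copy())


def seed_tumour(grid: GridSpec, params: CellParams,
                rng: np.random.Generator) -> CellGrid:
    """Place ``n_seed_cells`` proliferating cells with random ages in the
    central ``seed_region``³ subregion, without overlap."""
    cells = CellGrid.empty(grid)
    n = params.n_seed_cells
    if n == 0:
        return cells
    r = params.seed_region
    lo = [(s - r) // 2 for s in grid.shape]
    coords = np.array([(i, j, k)
                       for i in range(lo[0], lo[0] + r)
                       for j in range(lo[1], lo[1] + r)
                       for k in range(lo[2], lo[2] + r)], dtype=np.int64)
    if n > len(coords):
        raise ValueError(
            f"cannot place {n} seed cells in a {r}^3 central region")
    chosen = coords[rng.choice(len(coords), size=n, replace=False)]
    ages = rng.integers(1, params.T_TC + 1, size=n)
    for (i, j, k), age in zip(chosen, ages):
        cells.phenotype[i, j, k] = P
        cells.age[i, j, k] = age
        cells.ever_occupied[i, j, k] = True
    return cells


def consumption_field(cells: CellGrid, chem: ChemicalParams) -> np.ndarray:
    """Per-voxel O2 consumption demand, µmol/s (γ scaled by phenotype)."""
    factors = np.array([O2_CONSUMPTION_FACTOR[c] for c in range(4)])
    return chem.gamma * factors[cells.phenotype]


def mde_production_field(cells: CellGrid, chem: ChemicalParams) -> np.ndarray:
    """Per-voxel MDE production by tumour cells, µmol/s (µ_T scaled)."""
    factors = np.array([MDE_PRODUCTION_FACTOR[c] for c in range(4)])
    return chem.mu_T * factors[cells.phenotype]


def update_cells(cells: CellGrid, o2_normalised: np.ndarray,
                 params: CellParams, rng: np.random.Generator) -> dict:
    """One automaton step over all occupied voxels, in randomised order.

    Rules per live (P/Q) cell at local normalised O2 ``c``:

    1. ``c < theta_surv`` → necrosis (deterministic).
    2. else if ``c >= theta_prol`` and an empty 6-neighbour exists →
       divide with probability ``T_age/T_TC``; on success the parent is
       replaced by an age-1 daughter and a second age-1 daughter takes a
       uniformly chosen empty neighbour; on failure the age increments
       (capped at T_TC) and the cell is proliferating.
    3. otherwise quiescent (age retained and incremented up to the cap).

    Necrotic cells past ``necrotic_lifetime`` are cleared with
    probability ``p_clear``.  Returns an event tally for bookkeeping.
    """
    shape = cells.phenotype.shape
    ph = cells.phenotype
    occupied = np.argwhere(ph != EMPTY)
    events = {"divisions": 0, "necrosed": 0, "cleared": 0,
              "to_quiescent": 0, "to_proliferating": 0}
    if len(occupied) == 0:
        return events
    order = rng.permutation(len(occupied))

    for idx in order:
        i, j, k = occupied[idx]
        state = ph[i, j, k]
        if state == EMPTY:      # cleared earlier this sweep (cannot happen
            continue            # for live cells; defensive)
        if state == N:
            cells.necrotic_duration[i, j, k] += 1
            if (cells.necrotic_duration[i, j, k] > params.necrotic_lifetime
                    and rng.random() < params.p_clear):
                ph[i, j, k] = EMPTY
                cells.necrotic_duration[i, j, k] = 0
                events["cleared"] += 1
            continue

        c = o2_normalised[i, j, k]
        if c < params.theta_surv:
            ph[i, j, k] = N
            cells.age[i, j, k] = 0
            cells.necrotic_duration[i, j, k] = 0
            events["necrosed"] += 1
            continue

        # collect empty von-Neumann neighbours
        free: list[tuple[int, int, int]] = []
        for di, dj, dk in _NEIGHBOUR_OFFSETS:
            ni, nj, nk = i + di, j + dj, k + dk
            if (0 <= ni < shape[0] and 0 <= nj < shape[1]
                    and 0 <= nk < shape[2] and ph[ni, nj, nk] == EMPTY):
                free.append((ni, nj, nk))

        if c >= params.theta_prol and free:
            if ph[i, j, k] == Q:
                events["to_proliferating"] += 1
            ph[i, j, k] = P
            if rng.random() < cells.age[i, j, k] / params.T_TC:
                site = free[rng.integers(len(free))]
                ph[site] = P
                cells.age[site] = 1
                cells.ever_occupied[site] = True
                cells.age[i, j, k] = 1
                events["divisions"] += 1
            else:
                cells.age[i, j, k] = min(cells.age[i, j, k] + 1, params.T_TC)
        else:
            if ph[i, j, k] == P:
                events["to_quiescent"] += 1
            ph[i, j, k] = Q
            cells.age[i, j, k] = min(cells.age[i, j, k] + 1, params.T_TC)
    return events
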