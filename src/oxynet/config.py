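"""Run configuration: parameter blocks, validation, YAML round-trip.

Every physical default is stored in the internal unit system (µm, s, mmHg,
µmol; see :mod:`oxynet.units`).  Constructors below perform the visible
conversion from the customary literature units in which the values are
usually quoted.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import units as U


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration."""


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Cubic lattice of voxels; lattice nodes coincide with voxel centres."""

    n_x: int = 100
    n_y: int = 100
    n_z: int = 100
    spacing: float = 10.0  #: lattice constant Δl, µm

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) < 4:
            raise ConfigError("grid dimensions must all be >= 4")
        if self.spacing <= 0:
            raise ConfigError("lattice spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def n_voxels(self) -> int:
        return self.n_x * self.n_y * self.n_z

    @property
    def voxel_volume(self) -> float:
        """µm³ per voxel."""
        return self.spacing ** 3

    @property
    def extent(self) -> tuple[float, float, float]:
        """Domain edge lengths in µm."""
        return (self.n_x * self.spacing, self.n_y * self.spacing,
                self.n_z * self.spacing)


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

#: arteriole order → (diameter µm, proportion of arterioles)
ARTERIOLE_DIAMETERS_UM = {1: 50.0, 2: 30.0, 3: 10.0}
ARTERIOLE_PROPORTIONS = (0.10, 0.20, 0.70)
CAPILLARY_DIAMETER_UM = 8.0

#: order codes used in segment arrays
ORDER_ART1, ORDER_ART2, ORDER_ART3, ORDER_CAP = 1, 2, 3, 4
ORDER_NAMES = {ORDER_ART1: "arteriole-1", ORDER_ART2: "arteriole-2",
               ORDER_ART3: "arteriole-3", ORDER_CAP: "capillary"}


@dataclass
class NetworkParams:
    """Parameters of the procedurally built pre-existing arteriolar network."""

    #: spacing of parallel arteriole lines, in lattice units
    line_spacing: int = 10
    #: scaling of the number of arteriole lines (0.5 / 1.0 / 1.5 studied)
    mvd_multiplier: float = 1.0
    #: probability of a capillary bridge per adjacent arteriole pair per
    #: line_spacing-wide window along y
    capillary_link_prob: float = 0.3
    #: vessel wall thickness w, µm
    wall_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.mvd_multiplier <= 0:
            raise ConfigError("mvd_multiplier must be positive")
        if not 0.0 <= self.capillary_link_prob <= 1.0:
            raise ConfigError("capillary_link_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# haemodynamics
# ---------------------------------------------------------------------------

@dataclass
class FlowParams:
    #: osmotic reflection coefficient for plasma proteins σ_T
    sigma_T: float = 0.82
    #: colloid osmotic pressure of plasma π_v, mmHg
    pi_v: float = 20.0
    #: colloid osmotic pressure of interstitial fluid π_i, mmHg
    pi_i: float = 15.0
    #: interstitial hydraulic conductivity K, µm²/(mmHg·s)
    K: float = 4.13e-8 * U.CM2_TO_UM2
    #: exchange area density S/V, 1/µm
    S_over_V: float = 200.0 / U.CM_TO_UM
    #: inlet-to-outlet intravascular pressure difference, mmHg
    delta_P_drive: float = 3.5
    #: outlet-plane reference pressure, mmHg (only the difference is physical)
    P_outlet: float = 15.0
    #: plasma viscosity µ_p, mmHg·s  (1.2 cP)
    mu_plasma: float = 1.2 * U.CP_TO_MMHG_S
    #: inlet (systemic) haematocrit
    H_inlet: float = 0.45
    #: hydraulic wall permeability of mature (normal-tissue) vessels,
    #: µm/(mmHg·s); normal-tissue value from the same source as L_p^T
    Lp_normal: float = 0.36e-7 * U.CM_TO_UM
    #: Picard coupling tolerance on pressures, mmHg
    tol_couple: float = 1.0e-6
    max_picard_iter: int = 60
    #: interstitial CG solve tolerance (relative)
    tol_interstitial: float = 1.0e-10
    #: under-relaxation of the Picard update (1 = none)
    relax: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma_T <= 1.0:
            raise ConfigError("sigma_T must be in [0, 1]")
        if not 0.0 < self.H_inlet < 1.0:
            raise ConfigError("H_inlet must be in (0, 1)")
        for name in ("pi_v", "pi_i", "K", "S_over_V", "delta_P_drive",
                     "mu_plasma", "Lp_normal"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def osmotic_term(self) -> float:
        """σ_T(π_v − π_i), mmHg."""
        return self.sigma_T * (self.pi_v - self.pi_i)


# ---------------------------------------------------------------------------
# chemicals
# ---------------------------------------------------------------------------

@dataclass
class ChemicalParams:
    #: MDE diffusion coefficient D_m, µm²/s
    D_m: float = 1.0e-9 * U.CM2_TO_UM2
    #: ECM degradation coefficient δ, µm³/(µmol·s)
    #: (1.3e2 per molar per second; 1 M⁻¹s⁻¹ = 1e9 µm³/(µmol·s))
    delta_ecm: float = 1.3e2 * 1.0e9
    #: MDE production by a proliferating tumour cell µ_T, µmol/(cell·s)
    mu_T: float = 1.7e-18 * U.MOL_TO_UMOL
    #: MDE production by an endothelial cell µ_E, µmol/(cell·s)
    mu_E: float = 0.3e-18 * U.MOL_TO_UMOL
    #: MDE decay coefficient λ, 1/s
    lambda_mde: float = 1.7e-8
    #: tissue oxygen diffusion coefficient D_o, µm²/s
    D_o: float = 1.0e-5 * U.CM2_TO_UM2
    #: O2 consumption of a proliferating cell γ, µmol/(cell·s)
    gamma: float = 6.25e-17 * U.MOL_TO_UMOL
    #: Bunsen solubility α, µmol/(µm³·mmHg)
    alpha: float = 1.27e-15
    #: haemoglobin concentration within an RBC, µmol/µm³ (0.0203 mol/L)
    C_Hb: float = 0.0203 * U.MOLAR_TO_UMOL_PER_UM3
    #: oxyhaemoglobin half-saturation partial pressure, mmHg
    P50: float = 26.0
    #: Hill exponent of the saturation curve
    hill_n: float = 2.7
    #: inlet free-O2 partial pressure, mmHg (defines the normalisation scale)
    P_O2_inlet: float = 100.0
    #: wall O2 transfer velocity of a mature vessel, µm/s; scales with the
    #: segment's hydraulic permeability (h = h_ref · Lp/Lp_normal)
    wall_o2_transfer_ref: float = 5.0
    #: inner iteration step for the quasi-steady chemical solve, s
    inner_dt: float = 5.0
    #: relative-change convergence tolerance of the inner iteration
    tol_chem: float = 1.0e-6
    max_inner_iter: int = 5000
    #: refresh the intravascular sweep every this many inner iterations
    #: (the frozen exchange coefficients change slowly; > 1 trades a
    #: slightly stale vascular chain for fewer sequential sweeps)
    sweep_every: int = 2
    #: fixed deposit rate per segment in point-source mode, µmol/s
    point_source_rate: float = 1.0e-12

    def __post_init__(self) -> None:
        if self.inner_dt <= 0:
            raise ConfigError("inner_dt must be positive")
        for name in ("D_m", "D_o", "alpha", "C_Hb", "P50", "hill_n"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def C_O2_inlet(self) -> float:
        """Inlet free-O2 concentration, µmol/µm³ (α·P_O2_inlet)."""
        return self.alpha * self.P_O2_inlet

    @property
    def c50(self) -> float:
        """Free-O2 concentration at half Hb saturation, µmol/µm³."""
        return self.alpha * self.P50


# ---------------------------------------------------------------------------
# tumour cells
# ---------------------------------------------------------------------------

@dataclass
class CellParams:
    #: proliferation O2 threshold, on the normalised (c/c_inlet) scale
    theta_prol: float = 0.30
    #: survival O2 threshold, normalised scale
    theta_surv: float = 0.05
    #: proliferation time T_TC in simulation steps (9 h at 1.5 h/step)
    T_TC: int = 6
    #: steps a necrotic cell persists before it may be cleared (45 h)
    necrotic_lifetime: int = 30
    #: per-step clearance probability of an over-age necrotic cell
    p_clear: float = 0.20
    #: number of proliferating seed cells placed initially
    n_seed_cells: int = 20
    #: edge length (voxels) of the central seeding subregion
    seed_region: int = 5

    def __post_init__(self) -> None:
        if not self.theta_surv < self.theta_prol:
            raise ConfigError("theta_surv must be < theta_prol")
        if not 0.0 <= self.p_clear <= 1.0:
            raise ConfigError("p_clear must be in [0, 1]")
        if self.T_TC < 1:
            raise ConfigError("T_TC must be >= 1")


# ---------------------------------------------------------------------------
# vessel dynamics
# ---------------------------------------------------------------------------

@dataclass
class VesselDynParams:
    #: cooption dilation rate, µm/h
    dilation_rate: float = 0.4
    #: maximum dilated radius R_max, µm
    R_max: float = 20.0
    #: hydraulic wall permeability in tumour tissue L_p^T, µm/(mmHg·s)
    Lp_tumour: float = 2.8e-7 * U.CM_TO_UM
    #: compliance coefficient E, mmHg
    E: float = 6.5
    #: compliance exponent b
    b: float = 0.1
    #: collapse pressure P_c, mmHg
    P_c: float = 2.0
    #: WSS collapse threshold as a fraction of f0
    tau_crit_frac: float = 0.5
    #: per-step collapse probability per unit low-WSS duration
    p_collapse_unit: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_crit_frac < 1.0:
            raise ConfigError("tau_crit_frac must be in (0, 1)")
        for name in ("dilation_rate", "R_max", "Lp_tumour", "E", "b"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# whole-run configuration
# ---------------------------------------------------------------------------

OXYGEN_MODES = ("flow_dependent", "point_source")


@dataclass
class SimConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    network: NetworkParams = field(default_factory=NetworkParams)
    flow: FlowParams = field(default_factory=FlowParams)
    chem: ChemicalParams = field(default_factory=ChemicalParams)
    cells: CellParams = field(default_factory=CellParams)
    vessel: VesselDynParams = field(default_factory=VesselDynParams)
    #: number of outer simulation steps (each 1.5 h)
    n_steps: int = 200
    #: outer step duration, hours
    step_hours: float = 1.5
    oxygen_mode: str = "flow_dependent"
    #: independent RNG stream seeds
    seed_network: int = 1
    seed_cells: int = 2
    seed_collapse: int = 3
    #: write a snapshot every `snapshot_every` steps (0 = never)
    snapshot_every: int = 0
    #: enable the cooption/dilation, remodelling and WSS-collapse stages
    #: individually (useful to disable in controlled experiments)
    enable_cooption: bool = True
    enable_remodelling: bool = True
    enable_collapse: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.step_hours <= 0:
            raise ConfigError("step_hours must be positive")
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        if self.oxygen_mode not in OXYGEN_MODES:
            raise ConfigError(
                f"oxygen_mode must be one of {OXYGEN_MODES}, "
                f"got {self.oxygen_mode!r}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        blocks = {"grid": GridSpec, "network": NetworkParams,
                  "flow": FlowParams, "chem": ChemicalParams,
                  "cells": CellParams, "vessel": VesselDynParams}
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in blocks:
                if not isinstance(val, dict):
                    raise ConfigError(f"block {key!r} must be a mapping")
                known = {f.name for f in dataclasses.fields(blocks[key])}
                unknown = set(val) - known
                if unknown:
                    raise ConfigError(
                        f"unknown keys in block {key!r}: {sorted(unknown)}")
                kwargs[key] = blocks[key](**val)
            else:
                known = {f.name for f in dataclasses.fields(cls)}
                if key not in known:
                    raise ConfigError(f"unknown configuration key {key!r}")
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)
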