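"""Physical constants, kinetic parameters, and their derivations.

Houses the fluid and oxygen parameter sets for the perfusion-chamber model
and the bookkeeping that turns cell loadings into Michaelis–Menten maximal
consumption rates (volumetric for cells suspended/settled in the vessel,
areal for cells adherent on scaffold surfaces).

Default values describe the 8 cm culture chamber: water-like medium,
dissolved-oxygen diffusivity 3×10⁻⁹ m²·s⁻¹, interface equilibrium
concentration 0.214 mol·m⁻³, Henry constant 932.4 atm·L·mol⁻¹, MM constant
5.6 mmHg, and a per-cell uptake of 2 nmol·min⁻¹ per 10⁶ cells (SAOS-2
osteosarcoma line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from . import units


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties (defaults mimic water / culture medium)."""

    density: float = 1000.0  # kg/m³
    dynamic_viscosity: float = 1e-3  # Pa·s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class OxygenParams:
    """Dissolved-oxygen transport and uptake parameters.

    Attributes
    ----------
    D : oxygen diffusivity in aqueous medium, m²·s⁻¹.
    Km_mmHg : Michaelis–Menten half-saturation constant, quoted as a
        partial pressure (mmHg) as is conventional in the oxygen-uptake
        literature; converted to concentration via Henry's law.
    C0 : dissolved concentration at the air–liquid interface, mol·m⁻³.
    K_O2 : Henry's-law constant, atm·L·mol⁻¹.
    per_cell_rate : uptake rate, nmol·min⁻¹ per 10⁶ cells.
    """

    D: float = 3e-9
    Km_mmHg: float = 5.6
    C0: float = 0.214
    K_O2: float = 932.4
    per_cell_rate: float = 2.0

    def __post_init__(self) -> None:
        for name in ("D", "Km_mmHg", "C0", "K_O2", "per_cell_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def Km_c(self) -> float:
        """MM constant expressed as a concentration, mol·m⁻³."""
        return km_to_concentration(self.Km_mmHg, self.K_O2)


def henry_pressure(c: float, K_O2: float) -> float:
    """Partial pressure (atm) in equilibrium with dissolved concentration.

    P = K_O2 · C with C expressed in mol·L⁻¹ (input is mol·m⁻³).
    """
    if c < 0 or K_O2 < 0:
        raise ValueError("concentration and Henry constant must be non-negative")
    return K_O2 * (c / 1000.0)


def henry_concentration(p_atm: float, K_O2: float) -> float:
    """Inverse of :func:`henry_pressure`: dissolved mol·m⁻³ from atm."""
    if p_atm < 0 or K_O2 <= 0:
        raise ValueError("pressure must be non-negative, Henry constant positive")
    return p_atm / K_O2 * 1000.0


def km_to_concentration(km_mmhg: float, K_O2: float) -> float:
    """Convert an MM constant quoted in mmHg to mol·m⁻³ via Henry's law."""
    if km_mmhg < 0:
        raise ValueError("Km must be non-negative")
    return henry_concentration(units.mmhg_to_atm(km_mmhg), K_O2)


class LoadingMode(str, Enum):
    bulk = "bulk"
    per_scaffold = "per_scaffold"


@dataclass(frozen=True)
class CellLoading:
    """Cell numbers and the volume/area they are referred to.

    ``bulk`` mode: ``n_cells`` is the total cell number in the vessel and
    consumption is homogenised over ``vessel_volume``.  ``per_scaffold``
    mode: ``n_cells`` is the count per scaffold; consumption is referred to
    the nominal scaffold surface area (``area_per_scaffold``).
    """

    mode: LoadingMode
    n_cells: float
    n_scaffolds: int = 0
    vessel_volume: float = 0.0  # m³
    area_per_scaffold: float = 0.0  # m²

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("cell count must be non-negative")


class ReactionMode(str, Enum):
    volumetric = "volumetric"
    surface = "surface"


@dataclass(frozen=True)
class ReactionSpec:
    """A Michaelis–Menten oxygen sink.

    ``vmax`` is mol·m⁻³·s⁻¹ for volumetric sinks (applied in fluid cells)
    or mol·m⁻²·s⁻¹ for surface sinks (applied as a flux on fluid faces
    adjacent to scaffold solid).  ``km_c`` is in mol·m⁻³.  ``provenance``
    records the loading the rate was derived from.  ``region`` optionally
    restricts a volumetric sink to a boolean cell mask (default: all fluid).
    """

    mode: ReactionMode
    vmax: float
    km_c: float
    provenance: dict = field(default_factory=dict)
    region: object | None = None  # boolean ndarray over the domain grid

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("Vmax must be non-negative")
        if self.km_c <= 0:
            raise ValueError("Km must be positive")


def volumetric_vmax(loading: CellLoading, params: OxygenParams) -> float:
    """Maximal volumetric uptake rate, mol·m⁻³·s⁻¹.

    Per-cell rate × total cell number, divided by the vessel fluid volume.
    """
    if loading.mode is not LoadingMode.bulk:
        raise ValueError("volumetric_vmax requires a bulk loading")
    if loading.vessel_volume <= 0:
        raise ValueError("vessel volume must be positive")
    total_rate = (
        units.nmol_per_min_to_mol_per_s(params.per_cell_rate)
        * loading.n_cells
        / 1e6
    )
    return total_rate / loading.vessel_volume


def areal_vmax(loading: CellLoading, params: OxygenParams) -> float:
    """Maximal areal uptake rate on scaffold surfaces, mol·m⁻²·s⁻¹.

    (cells per scaffold × number of scaffolds) × per-cell rate, divided by
    the total nominal scaffold surface area (n_scaffolds × area each); the
    scaffold count cancels algebraically but both factors are kept as the
    derivation is usually stated this way.
    """
    if loading.mode is not LoadingMode.per_scaffold:
        raise ValueError("areal_vmax requires a per-scaffold loading")
    if loading.area_per_scaffold <= 0 or loading.n_scaffolds <= 0:
        raise ValueError("scaffold count and area must be positive")
    total_rate = (
        units.nmol_per_min_to_mol_per_s(params.per_cell_rate)
        * loading.n_cells
        * loading.n_scaffolds
        / 1e6
    )
    total_area = loading.n_scaffolds * loading.area_per_scaffold
    return total_rate / total_area


def depletion_time_estimate(c0: float, vmax_volumetric: float) -> float:
    """Zeroth-order depletion time c0/Vmax, s.  A timescale bound used to
    pick integration horizons; actual MM depletion is slower near Km."""
    if vmax_volumetric <= 0:
        raise ValueError("Vmax must be positive")
    return c0 / vmax_volumetric
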