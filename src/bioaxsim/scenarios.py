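"""Runnable simulation scenarios and analytic test fixtures.

``paper_scenario`` builds the three chamber-scale cases studied with the
8 cm perfusion bioreactor:

* ``bulk_11M`` — 11×10⁶ cells consuming oxygen homogeneously throughout
  the 110 mL vessel (volumetric MM sink), no scaffolds;
* ``scaffolds_400k`` — 12 strut-lattice scaffolds (~50 % porosity) seeded
  at 4×10⁵ cells each, consumption applied on scaffold surfaces;
* ``scaffolds_4M`` — the same geometry at 4×10⁶ cells per scaffold.

All use water-like medium, 80 mL/min recirculating flow through 1.6 mm
ports, and quarter symmetry.  ``analytic_fixture`` supplies the small
closed-form cases used as solver oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import yaml

from . import units
from .geometry import (
    ChamberSpec,
    Label,
    ScaffoldSpec,
    ScaffoldVariant,
    VoxelDomain,
    build_chamber_domain,
    generate_sphere_subtracted_scaffold,
    generate_strut_scaffold,
)
from .params import (
    CellLoading,
    FluidProps,
    LoadingMode,
    OxygenParams,
    ReactionMode,
    ReactionSpec,
    areal_vmax,
    volumetric_vmax,
)
from .flow import FlowSolution, solve_steady_flow
from .transport import TransportSolution, solve_transport

PAPER_SCENARIOS = ("bulk_11M", "scaffolds_400k", "scaffolds_4M")
FIXTURE_KINDS = (
    "slab_consumption",
    "slab_first_order",
    "poiseuille_pipe",
    "couette",
    "well_mixed_mm",
    "closed_box",
)


@dataclass
class ScenarioConfig:
    """A fully specified, runnable chamber case."""

    name: str
    chamber: ChamberSpec
    loading: CellLoading
    scaffold: ScaffoldSpec | None = None
    fluid: FluidProps = field(default_factory=FluidProps)
    oxygen: OxygenParams = field(default_factory=OxygenParams)
    flow_rate: float = units.ml_per_min_to_m3_per_s(80.0)  # device rate, m³/s
    resolution: float = 2e-3
    seed: int = 0
    schedule: dict | None = None  # None → steady state

    def __post_init__(self) -> None:
        has_scaffold = self.scaffold is not None
        per_scaffold = self.loading.mode is LoadingMode.per_scaffold
        if has_scaffold != per_scaffold:
            raise ValueError(
                "scaffold geometry must be present exactly when the loading "
                "is per-scaffold"
            )

    def reactions(self) -> list[ReactionSpec]:
        """Derive the MM sink(s) implied by the cell loading."""
        km = self.oxygen.Km_c
        if self.loading.mode is LoadingMode.bulk:
            vmax = volumetric_vmax(self.loading, self.oxygen)
            return [ReactionSpec(
                ReactionMode.volumetric, vmax, km,
                provenance={
                    "n_cells": self.loading.n_cells,
                    "vessel_volume_m3": self.loading.vessel_volume,
                },
            )]
        vmax = areal_vmax(self.loading, self.oxygen)
        return [ReactionSpec(
            ReactionMode.surface, vmax, km,
            provenance={
                "cells_per_scaffold": self.loading.n_cells,
                "n_scaffolds": self.loading.n_scaffolds,
                "area_per_scaffold_m2": self.loading.area_per_scaffold,
            },
        )]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["loading"]["mode"] = self.loading.mode.value
        if self.scaffold is not None:
            d["scaffold"]["variant"] = self.scaffold.variant.value
            d["scaffold"]["dims"] = list(self.scaffold.dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["chamber"] = ChamberSpec(**d["chamber"])
        ld = dict(d["loading"])
        ld["mode"] = LoadingMode(ld["mode"])
        d["loading"] = CellLoading(**ld)
        if d.get("scaffold") is not None:
            sc = dict(d["scaffold"])
            sc["variant"] = ScaffoldVariant(sc["variant"])
            sc["dims"] = tuple(sc["dims"])
            d["scaffold"] = ScaffoldSpec(**sc)
        d["fluid"] = FluidProps(**d["fluid"])
        d["oxygen"] = OxygenParams(**d["oxygen"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))


def paper_scenario(name: str, resolution: float = 2e-3) -> ScenarioConfig:
    """Construct one of the standard chamber scenarios by name."""
    oxygen = OxygenParams()
    if name == "bulk_11M":
        return ScenarioConfig(
            name=name,
            chamber=ChamberSpec(n_scaffolds=0),
            loading=CellLoading(
                LoadingMode.bulk, 11e6, vessel_volume=110e-6
            ),
            oxygen=oxygen,
            resolution=resolution,
        )
    if name in ("scaffolds_400k", "scaffolds_4M"):
        n_cells = 4e5 if name == "scaffolds_400k" else 4e6
        return ScenarioConfig(
            name=name,
            chamber=ChamberSpec(n_scaffolds=12),
            loading=CellLoading(
                LoadingMode.per_scaffold, n_cells,
                n_scaffolds=12, area_per_scaffold=0.01,
            ),
            scaffold=ScaffoldSpec(
                target_porosity=0.50,
                variant=ScaffoldVariant.strut_lattice,
                pore_spacing=2.5e-3,
            ),
            oxygen=oxygen,
            resolution=resolution,
        )
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(PAPER_SCENARIOS)}"
    )


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    domain: VoxelDomain
    flow: FlowSolution
    transport: TransportSolution
    summary: "object"  # reporting.SummaryStats; kept loose to avoid cycle
    reactions: list[ReactionSpec]


def build_scenario_domain(config: ScenarioConfig) -> VoxelDomain:
    blocks = []
    if config.scaffold is not None:
        spec = config.scaffold
        if spec.variant is ScaffoldVariant.strut_lattice:
            blocks = [generate_strut_scaffold(spec)]
        else:
            blocks = [generate_sphere_subtracted_scaffold(
                ScaffoldSpec(**{**asdict(spec), "seed": config.seed,
                                "variant": spec.variant})
            )]
    return build_chamber_domain(
        config.chamber, blocks, resolution=config.resolution
    )


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """End-to-end: geometry → steady flow → oxygen transport → summary."""
    from .reporting import summarize_field  # local import avoids a cycle

    domain = build_scenario_domain(config)
    frac = 0.25 if config.chamber.quarter_symmetry else 1.0
    flow = solve_steady_flow(domain, config.fluid, config.flow_rate * frac)
    transport = solve_transport(
        domain, flow, config.oxygen, config.reactions(),
        schedule=config.schedule,
    )
    summary = summarize_field(transport.c, domain)
    return ScenarioResult(
        config=config, domain=domain, flow=flow, transport=transport,
        summary=summary, reactions=config.reactions(),
    )


# ---------------------------------------------------------------------------
# analytic fixtures (solver oracles)

@dataclass
class Fixture:
    """A small domain plus the exact reference it must reproduce."""

    kind: str
    domain: VoxelDomain
    oxygen: OxygenParams
    fluid: FluidProps
    reactions: list[ReactionSpec]
    flow_rate: float = 0.0
    moving_wall: tuple | None = None
    schedule: dict | None = None
    reference: Callable | dict | None = None
    include_advection: bool = True
    notes: str = ""


def _box_labels(nf: tuple[int, int, int]) -> np.ndarray:
    """All-wall grid with an interior fluid box of shape ``nf``."""
    lab = np.full(tuple(n + 2 for n in nf), int(Label.WALL), np.uint8)
    lab[1:-1, 1:-1, 1:-1] = int(Label.FLUID)
    return lab


def analytic_fixture(kind: str) -> Fixture:
    oxygen = OxygenParams()
    fluid = FluidProps()
    if kind == "slab_consumption":
        n = 50
        L = 1e-3
        h = L / n
        lab = _box_labels((n, 1, 1))
        lab[0, 1, 1] = int(Label.INTERFACE)  # Dirichlet C0 at x = 0
        dom = VoxelDomain(lab, h, origin=np.array([-h, -h, -h]))
        # Km far below the minimum concentration → effectively zeroth order;
        # Vmax chosen so the sink depletes most of C0 across the slab while
        # c(L) = C0 − (Vmax/D) L²/2 ≈ 0.047 stays positive.
        vmax = 1e-3
        rx = [ReactionSpec(ReactionMode.volumetric, vmax, 1e-9)]
        C0, D = oxygen.C0, oxygen.D

        def ref(x):
            return C0 - (vmax / D) * (L * np.asarray(x) - np.asarray(x) ** 2 / 2)

        return Fixture(kind, dom, oxygen, fluid, rx, reference=ref,
                       notes="steady diffusion with zeroth-order sink")
    if kind == "slab_first_order":
        # Km ≫ C0 → linear uptake rate (Vmax/Km)·c with closed form
        # c(x) = C0 cosh(κ(L−x))/cosh(κL), κ = sqrt(Vmax/(Km·D)); the
        # solution is non-polynomial, so truncation error is visible and
        # grid-convergence order can be measured.
        n = 25
        L = 1e-3
        h = L / n
        lab = _box_labels((n, 1, 1))
        lab[0, 1, 1] = int(Label.INTERFACE)
        dom = VoxelDomain(lab, h, origin=np.array([-h, -h, -h]))
        km = 1e6  # ≫ C0 so the MM rate is linear to ~2×10⁻⁷ relative
        kr = 5e-3  # first-order rate constant Vmax/Km, 1/s
        rx = [ReactionSpec(ReactionMode.volumetric, kr * km, km)]
        C0, D = oxygen.C0, oxygen.D
        kappa = math.sqrt(kr / D)

        def ref(x):
            x = np.asarray(x)
            return C0 * np.cosh(kappa * (L - x)) / math.cosh(kappa * L)

        return Fixture(kind, dom, oxygen, fluid, rx, reference=ref,
                       notes="steady diffusion with first-order sink")
    if kind == "poiseuille_pipe":
        d = 1.6e-3
        n_across = 12
        h = d / n_across
        length = 10 * d
        nz = round(length / h)
        nx = n_across + 2
        lab = np.full((nx, nx, nz + 2), int(Label.WALL), np.uint8)
        c = nx * h / 2.0
        xs = (np.arange(nx) + 0.5) * h - c
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        disk = X**2 + Y**2 < (d / 2) ** 2
        lab[disk, 1:nz + 1] = int(Label.FLUID)
        lab[disk, 0] = int(Label.INLET)
        lab[disk, nz + 1] = int(Label.OUTLET)
        dom = VoxelDomain(lab, h)
        Q = units.ml_per_min_to_m3_per_s(80.0)
        area = math.pi * (d / 2) ** 2
        u_mean = Q / area
        ref = {
            "u_mean": u_mean,                      # 0.663 m/s
            "centerline_ratio": 2.0,
            "tau_wall": 4 * fluid.dynamic_viscosity * u_mean / (d / 2),
            "length": length,
        }
        return Fixture(
            kind, dom, oxygen, fluid, [], flow_rate=Q, reference=ref,
            include_advection=False,
            notes=(
                "laminar pipe flow against the Poiseuille closed form; "
                "solved in the creeping-flow limit, where the profile "
                "develops within ~1 diameter — in fully developed parallel "
                "flow the convective term vanishes identically, so the "
                "developed-region closed form is unchanged (at the physical "
                "Reynolds number ≈10³ the entrance itself would span ~10² "
                "diameters)"
            ),
        )
    if kind == "couette":
        # shear-driven closed cavity: top wall moves, net flux zero.
        # Between the plates (away from the end walls) the exact profile is
        # u(z) = U (3 z²/H² − 2 z/H), giving τ = 4 μU/H at the moving wall
        # and 2 μU/H at the fixed wall.
        H = 1e-3
        nzf = 10
        h = H / nzf
        nxf = 100
        lab = _box_labels((nxf, 1, nzf))
        lab[:, 0, :] = int(Label.SYMMETRY)
        lab[:, 2, :] = int(Label.SYMMETRY)
        U = 1e-3
        dom = VoxelDomain(lab, h)
        moving = np.zeros(lab.shape, dtype=bool)
        moving[:, :, nzf + 1] = lab[:, :, nzf + 1] == int(Label.WALL)
        mu = fluid.dynamic_viscosity

        def ref(z):
            z = np.asarray(z)
            return U * (3 * z**2 / H**2 - 2 * z / H)

        fx = Fixture(kind, dom, oxygen, fluid, [],
                     moving_wall=(moving, (U, 0.0, 0.0)),
                     reference={"profile": ref, "tau_top": 4 * mu * U / H,
                                "tau_bottom": 2 * mu * U / H, "gap": H,
                                "speed": U},
                     notes="shear-driven cavity (closed Couette)")
        return fx
    if kind == "well_mixed_mm":
        lab = _box_labels((1, 1, 1))
        h = 1e-3
        dom = VoxelDomain(lab, h)
        vmax = 3.33e-6
        km = oxygen.Km_c
        rx = [ReactionSpec(ReactionMode.volumetric, vmax, km)]

        def ref(times):
            from scipy.integrate import solve_ivp

            sol = solve_ivp(
                lambda t, y: [-vmax * y[0] / (y[0] + km)],
                (0.0, float(np.max(times))), [oxygen.C0],
                t_eval=np.atleast_1d(times), method="Radau",
                rtol=1e-10, atol=1e-14,
            )
            return sol.y[0]

        return Fixture(kind, dom, oxygen, fluid, rx,
                       schedule={"dt": 10.0, "t_end": 6e4}, reference=ref,
                       notes="well-mixed MM depletion vs ODE oracle")
    if kind == "closed_box":
        dom = VoxelDomain(_box_labels((4, 4, 4)), 1e-3)
        return Fixture(kind, dom, oxygen, fluid, [],
                       reference=(lambda: oxygen.C0),
                       notes="no sink, no flow: equilibrium preserved")
    raise ValueError(
        f"unknown fixture {kind!r}; valid kinds: {', '.join(FIXTURE_KINDS)}"
    )
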