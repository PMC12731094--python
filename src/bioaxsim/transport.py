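"""Dissolved-oxygen advection–diffusion–reaction on the voxel grid.

The concentration field obeys

    ∂c/∂t + ∇·(u c) = ∇·(D ∇c) − R(c),   R = Vmax·c/(c + Km)

with Michaelis–Menten (MM) uptake applied either volumetrically in fluid
cells or as a surface flux on fluid faces adjacent to scaffold solid.
Boundary conditions: fixed equilibrium concentration C0 on the air–liquid
interface (Henry's-law value), zero flux on walls and symmetry planes,
plug advective outflow at outlet ports, and a closed-loop recirculation
condition — the inlet concentration equals the outlet mean, as in a pump
loop whose tubing transit is fast compared with consumption.

The steady problem is solved by Picard iteration: the MM term is
linearized about the previous iterate (R ≈ [Vmax/(c_prev+Km)]·c), advection
is discretized with first-order upwinding and folded into the sparse
linear system, and the recirculated inlet value is refreshed each sweep.
The upwind/backward-Euler discretizations are M-matrices, so the discrete
maximum principle holds: with consuming sinks only, c stays in [0, C0].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow import FlowSolution
from .geometry import Label, VoxelDomain
from .params import (  # noqa: F401  (re-exported unit/equilibrium helpers)
    OxygenParams,
    ReactionMode,
    ReactionSpec,
    henry_concentration,
    henry_pressure,
    km_to_concentration,
)

_F = int(Label.FLUID)


def mm_rate(c, vmax: float, km_c: float):
    """Michaelis–Menten uptake rate Vmax·c/(c+Km); units follow ``vmax``.

    Saturates towards ``vmax`` for c ≫ Km and is linear (first order) for
    c ≪ Km.  Negative concentrations are rejected.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if km_c <= 0:
        raise ValueError("Km must be positive")
    out = vmax * c / (c + km_c)
    return out if out.ndim else float(out)


@dataclass
class TransportSolution:
    """Oxygen concentration field plus solve diagnostics.

    ``c`` is mol·m⁻³ on the full grid (NaN outside fluid).  ``history``
    holds (time or iteration, volume-mean c, cumulative consumed mol) rows.
    ``budget`` reports the steady balance: interface influx, port inflow
    and outflow, and total consumption (mol/s).
    """

    c: np.ndarray
    steady: bool
    time: float
    iterations: int
    history: list = field(default_factory=list)
    budget: dict = field(default_factory=dict)
    inlet_concentration: float = float("nan")

    def mean(self, domain: VoxelDomain) -> float:
        return float(np.nanmean(self.c[domain.fluid_mask]))


def _face_velocities(domain, velocity):
    shape = domain.shape
    if velocity is None:
        return (
            np.zeros((shape[0] + 1, shape[1], shape[2])),
            np.zeros((shape[0], shape[1] + 1, shape[2])),
            np.zeros((shape[0], shape[1], shape[2] + 1)),
        )
    return velocity.ux, velocity.uy, velocity.uz


_DIRS = [
    (0, (1, 0, 0), 1), (0, (-1, 0, 0), 0),
    (1, (0, 1, 0), 1), (1, (0, -1, 0), 0),
    (2, (0, 0, 1), 1), (2, (0, 0, -1), 0),
]


class _TransportOperator:
    """Caches the geometric stencil; rebuilds only the Picard-dependent
    reaction diagonal and recirculated inlet terms each sweep."""

    def __init__(self, domain, velocity, params, reactions, c_interface):
        self.domain = domain
        self.params = params
        self.c_interface = c_interface
        self.h = domain.spacing
        labels = domain.labels
        self.fluid = domain.fluid_mask
        self.cells = np.argwhere(self.fluid)
        self.n = len(self.cells)
        self.cid = -np.ones(labels.shape, dtype=np.int64)
        self.cid[self.fluid] = np.arange(self.n)
        self.volumetric = [r for r in reactions if r.mode is ReactionMode.volumetric]
        self.surface = [r for r in reactions if r.mode is ReactionMode.surface]

        ufaces = _face_velocities(domain, velocity)
        h = self.h
        i, j, k = self.cells.T

        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)
        rhs_const = np.zeros(self.n)
        inlet_coeff = np.zeros(self.n)  # × c_in → rhs
        out_cells = []
        out_q = []
        self.n_scaffold_faces_per_cell = np.zeros(self.n)
        D = params.D

        for a, step, side in _DIRS:
            fidx = self.cells.copy()
            fidx[:, a] += side  # face index on that side
            q = ufaces[a][fidx[:, 0], fidx[:, 1], fidx[:, 2]]
            q = q * (1.0 if side == 1 else -1.0)  # + = outflow
            nb = self.cells + np.array(step)
            nlab = labels[nb[:, 0], nb[:, 1], nb[:, 2]]

            m = nlab == _F
            if m.any():
                nbid = self.cid[nb[m, 0], nb[m, 1], nb[m, 2]]
                rid = np.arange(self.n)[m]
                # diffusion
                diag[rid] += D / h**2
                rows.append(rid); cols.append(nbid)
                vals.append(np.full(m.sum(), -D / h**2))
                # upwind advection
                qm = q[m]
                diag[rid] += np.maximum(qm, 0.0) / h
                rows.append(rid); cols.append(nbid)
                vals.append(np.minimum(qm, 0.0) / h)

            m = nlab == int(Label.INTERFACE)
            if m.any():
                rid = np.arange(self.n)[m]
                diag[rid] += 2.0 * D / h**2
                rhs_const[rid] += 2.0 * D / h**2 * c_interface

            m = nlab == int(Label.SCAFFOLD)
            if m.any():
                self.n_scaffold_faces_per_cell[np.arange(self.n)[m]] += 1.0

            m = nlab == int(Label.INLET)
            if m.any():
                rid = np.arange(self.n)[m]
                qi = q[m]  # negative = inflow
                inlet_coeff[rid] += np.maximum(-qi, 0.0) / h

            m = nlab == int(Label.OUTLET)
            if m.any():
                rid = np.arange(self.n)[m]
                qo = q[m]
                diag[rid] += np.maximum(qo, 0.0) / h
                out_cells.append(rid[qo > 0])
                out_q.append(qo[qo > 0])

        self.base_diag = diag
        self.rhs_const = rhs_const
        self.inlet_coeff = inlet_coeff
        if out_cells:
            self.out_cells = np.concatenate(out_cells)
            self.out_q = np.concatenate(out_q)
        else:
            self.out_cells = np.zeros(0, dtype=int)
            self.out_q = np.zeros(0)
        self.off_rows = np.concatenate(rows) if rows else np.zeros(0, dtype=int)
        self.off_cols = np.concatenate(cols) if cols else np.zeros(0, dtype=int)
        self.off_vals = np.concatenate(vals) if vals else np.zeros(0)

    def recirculation_coupling(self):
        """COO entries tying each inlet cell to the flux-weighted outlet
        mean: the closed-loop condition c_in = ⟨c⟩_outlet is linear in c and
        is imposed implicitly (an outer fixed point on c_in contracts at
        ~1 − consumed/recirculated per sweep, which is impractically slow
        for a loop that consumes ≲1 % of the recirculated oxygen)."""
        rows_i = np.nonzero(self.inlet_coeff > 0)[0]
        if len(rows_i) == 0 or len(self.out_cells) == 0:
            return None
        w = self.out_q / self.out_q.sum()
        rows = np.repeat(rows_i, len(self.out_cells))
        cols = np.tile(self.out_cells, len(rows_i))
        vals = -np.outer(self.inlet_coeff[rows_i], w).ravel()
        return rows, cols, vals

    def _volumetric_mask(self, spec):
        if spec.region is None:
            return 1.0
        return np.asarray(spec.region, bool)[
            self.cells[:, 0], self.cells[:, 1], self.cells[:, 2]
        ].astype(float)

    def reaction_diag(self, c_prev_cells):
        """Picard-linearized MM coefficient per cell (1/s)."""
        r = np.zeros(self.n)
        for spec in self.volumetric:
            r += self._volumetric_mask(spec) * spec.vmax / (
                c_prev_cells + spec.km_c
            )
        for spec in self.surface:
            r += (
                (spec.vmax / (c_prev_cells + spec.km_c))
                * self.n_scaffold_faces_per_cell
                / self.h
            )
        return r

    def matrix(self, c_prev_cells, extra_diag=0.0, implicit_recirc=False):
        diag = self.base_diag + self.reaction_diag(c_prev_cells) + extra_diag
        n = self.n
        rows = [self.off_rows, np.arange(n)]
        cols = [self.off_cols, np.arange(n)]
        vals = [self.off_vals, diag]
        if implicit_recirc:
            coup = self.recirculation_coupling()
            if coup is not None:
                rows.append(coup[0]); cols.append(coup[1]); vals.append(coup[2])
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return A.tocsc()

    def outlet_mean(self, c_cells) -> float:
        if len(self.out_cells) == 0 or self.out_q.sum() == 0:
            return float("nan")
        return float(
            np.sum(self.out_q * c_cells[self.out_cells]) / np.sum(self.out_q)
        )

    def consumption(self, c_cells) -> float:
        """Total MM consumption, mol/s, at the given state."""
        h = self.h
        tot = 0.0
        for spec in self.volumetric:
            tot += float(
                np.sum(
                    self._volumetric_mask(spec)
                    * mm_rate(c_cells, spec.vmax, spec.km_c)
                )
            ) * h**3
        for spec in self.surface:
            tot += float(
                np.sum(
                    mm_rate(c_cells, spec.vmax, spec.km_c)
                    * self.n_scaffold_faces_per_cell
                )
            ) * h**2
        return tot


def solve_transport(
    domain: VoxelDomain,
    velocity: FlowSolution | None,
    params: OxygenParams,
    reactions: list[ReactionSpec],
    *,
    c_interface: float | None = None,
    recirculate: bool = True,
    schedule: dict | None = None,
    steady_tol: float = 1e-9,
    max_picard: int = 200,
) -> TransportSolution:
    """Solve the oxygen transport equation on the domain.

    ``schedule=None`` solves directly for the steady state (Picard);
    ``schedule={"dt": ..., "t_end": ...}`` integrates in time with
    backward-Euler diffusion/reaction and upwind advection folded into the
    implicit system.  Initial condition and default interface value are the
    equilibrium concentration ``params.C0``.
    """
    domain.require_fluid()
    if c_interface is None:
        c_interface = params.C0
    op = _TransportOperator(domain, velocity, params, reactions, c_interface)
    C0 = params.C0
    c = np.full(op.n, C0)
    c_in = C0
    history = []

    if schedule is None:
        # closed equilibrium: with no Dirichlet surface, no outflow and no
        # sink the steady operator is pure-Neumann (singular) and the
        # conserved uniform initial state is the steady solution
        closed = (
            not op.volumetric and not op.surface
            and op.rhs_const.max() == 0.0 and len(op.out_cells) == 0
            and op.inlet_coeff.max() == 0.0
        )
        if closed:
            field_c = np.full(domain.shape, np.nan)
            field_c[op.fluid] = c
            return TransportSolution(
                c=field_c, steady=True, time=float("inf"), iterations=0,
                history=[(0, float(c.mean()), 0.0)],
                budget=_budget(op, c, c_in), inlet_concentration=c_in,
            )
        it = 0
        for it in range(1, max_picard + 1):
            A = op.matrix(c, implicit_recirc=recirculate)
            b = op.rhs_const.copy()
            if not recirculate:
                b += op.inlet_coeff * c_in
            c_new = spla.spsolve(A, b)
            delta = float(np.abs(c_new - c).max())
            c = c_new
            if recirculate:
                om = op.outlet_mean(c)
                if np.isfinite(om):
                    c_in = om
            history.append((it, float(c.mean()), op.consumption(c)))
            if delta < max(steady_tol, 1e-12 * C0):
                break
        sol_time = float("inf")
        steady = True
        iterations = it
    else:
        dt = float(schedule["dt"])
        t_end = float(schedule["t_end"])
        umax = 0.0
        if velocity is not None:
            umax = max(
                np.abs(velocity.ux).max(),
                np.abs(velocity.uy).max(),
                np.abs(velocity.uz).max(),
            )
        if umax > 0 and dt > 0.9 * domain.spacing / umax:
            raise ValueError(
                f"dt={dt:g} s violates the advective CFL limit; "
                f"use dt ≤ {0.9 * domain.spacing / umax:g} s"
            )
        t = 0.0
        consumed = 0.0
        iterations = 0
        while t < t_end - 1e-12:
            A = op.matrix(c, extra_diag=1.0 / dt)
            b = op.rhs_const + op.inlet_coeff * c_in + c / dt
            c = spla.spsolve(A, b)
            t += dt
            iterations += 1
            if recirculate:
                om = op.outlet_mean(c)
                if np.isfinite(om):
                    c_in = om
            consumed += op.consumption(c) * dt
            history.append((t, float(c.mean()), consumed))
        sol_time = t
        steady = False

    field_c = np.full(domain.shape, np.nan)
    field_c[op.fluid] = c
    budget = _budget(op, c, c_in)
    return TransportSolution(
        c=field_c, steady=steady, time=sol_time, iterations=iterations,
        history=history, budget=budget, inlet_concentration=c_in,
    )


def _budget(op, c_cells, c_in) -> dict:
    h = op.h
    # inlet_coeff is q/h per unit cell volume → flux = coeff · h³ · c_in
    inflow = float(np.sum(op.inlet_coeff * c_in) * h**3)
    outflow = float(np.sum(op.out_q * c_cells[op.out_cells]) * h**2)
    consumed = op.consumption(c_cells)
    D = op.params.D
    iface_coeff = np.zeros(op.n)
    labels = op.domain.labels
    for a, step, side in _DIRS:
        nb = op.cells + np.array(step)
        sel = labels[nb[:, 0], nb[:, 1], nb[:, 2]] == int(Label.INTERFACE)
        if sel.any():
            iface_coeff[sel] += 1.0
    iface = float(
        np.sum(iface_coeff * 2.0 * D / h**2 * (op.c_interface - c_cells)) * h**3
    )
    return {
        "inlet_mol_s": inflow,
        "outlet_mol_s": outflow,
        "interface_mol_s": iface,
        "consumed_mol_s": consumed,
        "closure": iface + inflow - outflow - consumed,
    }
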