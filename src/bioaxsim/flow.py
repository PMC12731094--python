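"""Steady laminar incompressible flow on a labeled voxel grid.

Momentum and continuity are discretized with finite volumes on a staggered
(MAC) grid: velocity components live on cell faces, pressure at cell
centers.  The steady state is obtained directly by solving the coupled
velocity–pressure saddle-point system with a sparse direct factorization;
the convective term is included by Picard (Oseen) iteration with
first-order upwinding, starting from the Stokes solution.  This sidesteps
pseudo-time marching, whose viscous equilibration time at chamber scale is
hours of physical time.

Boundary conditions follow the voxel labels: no-slip on walls and scaffold
solid, free slip on symmetry planes and the air–liquid interface (both
impermeable), uniform plug inflow across inlet faces, and uniform outflow
across outlet faces with the rate balanced exactly against the inflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Label, VoxelDomain
from .params import FluidProps

_FREE_SLIP = (int(Label.SYMMETRY), int(Label.INTERFACE))
_F = int(Label.FLUID)


@dataclass
class FlowSolution:
    """Converged steady flow field.

    ``ux, uy, uz`` are face-normal velocities on the staggered grid (m/s);
    ``p`` is cell-centered pressure (Pa, NaN outside fluid).  ``residual``
    is the relative change of velocity over the last Picard sweep and
    ``divergence`` the maximum discrete divergence over fluid cells (1/s).
    """

    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    p: np.ndarray
    residual: float
    iterations: int
    divergence: float
    spacing: float

    def speed_at_centers(self) -> np.ndarray:
        """Cell-centered speed magnitude."""
        cx = 0.5 * (self.ux[:-1] + self.ux[1:])
        cy = 0.5 * (self.uy[:, :-1] + self.uy[:, 1:])
        cz = 0.5 * (self.uz[:, :, :-1] + self.uz[:, :, 1:])
        return np.sqrt(cx**2 + cy**2 + cz**2)

    def velocity_at_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            0.5 * (self.ux[:-1] + self.ux[1:]),
            0.5 * (self.uy[:, :-1] + self.uy[:, 1:]),
            0.5 * (self.uz[:, :, :-1] + self.uz[:, :, 1:]),
        )


def _face_axes_slices(a: int, shape):
    """Slices into the padded label array giving the two cells of each
    face along axis ``a`` (face arrays have shape+1 along that axis)."""
    sl_l, sl_r = [], []
    for ax in range(3):
        if ax == a:
            sl_l.append(slice(0, shape[ax] + 1))
            sl_r.append(slice(1, shape[ax] + 2))
        else:
            sl_l.append(slice(1, shape[ax] + 1))
            sl_r.append(slice(1, shape[ax] + 1))
    return tuple(sl_l), tuple(sl_r)


class _FaceSet:
    """Per-axis face classification: DOF mask, prescribed values, labels."""

    def __init__(self, a, labels_padded, shape):
        sl_l, sl_r = _face_axes_slices(a, shape)
        self.labL = labels_padded[sl_l]
        self.labR = labels_padded[sl_r]
        self.fluidL = self.labL == _F
        self.fluidR = self.labR == _F
        self.dof = self.fluidL & self.fluidR
        self.one_fluid = self.fluidL ^ self.fluidR
        self.other = np.where(self.fluidL, self.labR, self.labL)
        # +1 when flow along +axis enters the fluid (fluid on the R side)
        self.sign_in = np.where(self.fluidR & ~self.fluidL, 1.0, -1.0)
        self.value = np.zeros(self.labL.shape)

    def set_port_values(self, q_in, q_out):
        m_in = self.one_fluid & (self.other == int(Label.INLET))
        m_out = self.one_fluid & (self.other == int(Label.OUTLET))
        self.value[m_in] = self.sign_in[m_in] * q_in
        self.value[m_out] = -self.sign_in[m_out] * q_out


def _count_port_faces(facesets):
    n_in = sum(
        int((fs.one_fluid & (fs.other == int(Label.INLET))).sum())
        for fs in facesets
    )
    n_out = sum(
        int((fs.one_fluid & (fs.other == int(Label.OUTLET))).sum())
        for fs in facesets
    )
    return n_in, n_out


def solve_steady_flow(
    domain: VoxelDomain,
    fluid: FluidProps,
    flow_rate: float,
    *,
    include_advection: bool = True,
    picard_max: int = 10,
    picard_tol: float = 1e-3,
    moving_wall: tuple[np.ndarray, tuple[float, float, float]] | None = None,
) -> FlowSolution:
    """Solve steady incompressible flow through the labeled domain.

    ``flow_rate`` (m³/s) is the volumetric rate through this domain's inlet
    faces (for a quarter-symmetry domain pass a quarter of the device
    rate).  ``moving_wall`` optionally prescribes a tangential velocity on
    a boolean mask of wall cells (shear-driven fixtures).
    """
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    domain.require_fluid()
    labels = domain.labels
    shape = labels.shape
    h = domain.spacing
    mu = fluid.dynamic_viscosity
    rho = fluid.density

    Lp = np.pad(labels, 1, constant_values=int(Label.WALL))
    faces = [_FaceSet(a, Lp, shape) for a in range(3)]

    n_in, n_out = _count_port_faces(faces)
    if flow_rate > 0:
        if n_in == 0 or n_out == 0:
            raise ValueError("domain needs inlet and outlet faces for flow")
        q_in = flow_rate / (n_in * h * h)
        q_out = (q_in * n_in) / n_out
    else:
        q_in = q_out = 0.0
    for fs in faces:
        fs.set_port_values(q_in, q_out)

    still = flow_rate == 0.0 and moving_wall is None
    p = np.full(shape, np.nan)
    p[domain.fluid_mask] = 0.0
    if still:
        return FlowSolution(
            ux=np.zeros(faces[0].value.shape),
            uy=np.zeros(faces[1].value.shape),
            uz=np.zeros(faces[2].value.shape),
            p=p, residual=0.0, iterations=0, divergence=0.0, spacing=h,
        )

    # connected fluid components: pin one pressure per component and check
    # that prescribed fluxes balance within each (else inlet and outlet are
    # hydraulically disconnected)
    comp, n_comp = ndi.label(domain.fluid_mask)
    _check_component_balance(faces, comp, n_comp, h, flow_rate)

    if moving_wall is not None:
        mw_mask, mw_vel = moving_wall
        mw_pad = np.pad(mw_mask, 1, constant_values=False)
    else:
        mw_pad, mw_vel = None, (0.0, 0.0, 0.0)

    # velocity DOF numbering, then pressures
    dof_idx, offset = [], 0
    for fs in faces:
        idx = -np.ones(fs.dof.shape, dtype=np.int64)
        idx[fs.dof] = offset + np.arange(int(fs.dof.sum()))
        offset += int(fs.dof.sum())
        dof_idx.append(idx)
    n_u = offset
    pid = -np.ones(shape, dtype=np.int64)
    fl = domain.fluid_mask
    pid[fl] = n_u + np.arange(int(fl.sum()))
    n_tot = n_u + int(fl.sum())

    u_prev = [fs.value.copy() for fs in faces]
    sol_prev = None
    iterations = 0
    residual = np.inf
    for it in range(max(1, picard_max if include_advection else 1)):
        adv = include_advection and it >= 0 and (sol_prev is not None)
        A, b = _assemble(
            faces, dof_idx, pid, comp, n_comp, labels, Lp, h, mu, rho,
            u_prev if adv else None, mw_pad, mw_vel, n_tot,
        )
        x = spla.spsolve(A.tocsc(), b)
        u_new = []
        for a, fs in enumerate(faces):
            arr = fs.value.copy()
            arr[fs.dof] = x[dof_idx[a][fs.dof]]
            u_new.append(arr)
        iterations = it + 1
        if sol_prev is not None:
            num = max(np.abs(u_new[a] - u_prev[a]).max() for a in range(3))
            den = max(max(np.abs(u) .max() for u in u_new), 1e-300)
            residual = num / den
        u_prev = u_new
        sol_prev = x
        if not include_advection:
            residual = 0.0
            break
        if residual < picard_tol:
            break

    p_vals = sol_prev[n_u:]
    p = np.full(shape, np.nan)
    p[fl] = p_vals
    sol = FlowSolution(
        ux=u_prev[0], uy=u_prev[1], uz=u_prev[2], p=p,
        residual=float(residual if np.isfinite(residual) else 0.0),
        iterations=iterations, divergence=0.0, spacing=h,
    )
    sol.divergence = max_divergence(sol, domain)
    return sol


def _check_component_balance(faces, comp, n_comp, h, flow_rate):
    """Every connected fluid component must have balanced prescribed flux;
    an imbalance means the inlet and outlet are hydraulically disconnected
    (no incompressible solution exists there)."""
    for c in range(1, n_comp + 1):
        net = 0.0
        for a, fs in enumerate(faces):
            pres = fs.one_fluid
            if not pres.any():
                continue
            fi = np.argwhere(pres)
            cells = fi.copy()
            is_L = fs.fluidL[pres]
            cells[:, a] -= np.where(is_L, 1, 0)  # fluid cell of each face
            mine = comp[cells[:, 0], cells[:, 1], cells[:, 2]] == c
            if not mine.any():
                continue
            sgn = np.where(is_L[mine], -1.0, 1.0)  # + = inflow into fluid
            net += float(np.sum(sgn * fs.value[pres][mine])) * h * h
        if abs(net) > max(1e-9 * flow_rate, 1e-20):
            raise ValueError(
                "inlet and outlet lie in disconnected fluid regions "
                f"(component {c} has net prescribed flux {net:.3e} m³/s)"
            )


_DIRS = [
    (0, (1, 0, 0)), (0, (-1, 0, 0)),
    (1, (0, 1, 0)), (1, (0, -1, 0)),
    (2, (0, 0, 1)), (2, (0, 0, -1)),
]


def _assemble(faces, dof_idx, pid, comp, n_comp, labels, Lp, h, mu, rho,
              u_adv, mw_pad, mw_vel, n_tot):
    rows, cols, vals = [], [], []
    b = np.zeros(n_tot)
    inv_h2 = 1.0 / (h * h)

    for a, fs in enumerate(faces):
        F = np.argwhere(fs.dof)
        if len(F) == 0:
            continue
        rid = dof_idx[a][fs.dof]
        diag = np.full(len(F), 6.0 * mu * inv_h2)

        # upwind advecting velocity components at these faces
        if u_adv is not None:
            U = _interp_face_velocity(a, F, u_adv)
        else:
            U = None

        for d, step in _DIRS:
            c_nb = np.full(len(F), -mu * inv_h2)
            if U is not None:
                Ud = U[d]
                upwind = (Ud > 0) if step[d] < 0 else (Ud < 0)
                c_nb = c_nb - np.where(upwind, rho * np.abs(Ud) / h, 0.0)
                diag = diag + np.where(upwind, rho * np.abs(Ud) / h, 0.0)
            nb = F + np.array(step)
            nb_dof = fs.dof[nb[:, 0], nb[:, 1], nb[:, 2]]
            nb_val = fs.one_fluid[nb[:, 0], nb[:, 1], nb[:, 2]]
            # DOF neighbors
            m = nb_dof
            if m.any():
                rows.append(rid[m])
                cols.append(dof_idx[a][nb[m, 0], nb[m, 1], nb[m, 2]])
                vals.append(c_nb[m])
            # valued neighbors
            m = nb_val & ~nb_dof
            if m.any():
                v = fs.value[nb[m, 0], nb[m, 1], nb[m, 2]]
                b[rid[m]] -= c_nb[m] * v
            # ghost neighbors (no fluid on either side of that face)
            m = ~nb_dof & ~nb_val
            if m.any():
                gl = fs.labL[nb[m, 0], nb[m, 1], nb[m, 2]]
                gr = fs.labR[nb[m, 0], nb[m, 1], nb[m, 2]]
                free = np.isin(gl, _FREE_SLIP) | np.isin(gr, _FREE_SLIP)
                idx_m = np.nonzero(m)[0]
                # free slip: ghost value = u_f
                fidx = idx_m[free]
                if len(fidx):
                    rows.append(rid[fidx])
                    cols.append(rid[fidx])
                    vals.append(c_nb[fidx])
                # no slip: ghost = 2*U_wall − u_f
                nidx = idx_m[~free]
                if len(nidx):
                    rows.append(rid[nidx])
                    cols.append(rid[nidx])
                    vals.append(-c_nb[nidx])
                    if mw_pad is not None and mw_vel[a] != 0.0:
                        uw = _wall_speed(a, fs, nb[nidx], mw_pad, mw_vel)
                        b[rid[nidx]] -= 2.0 * uw * c_nb[nidx]
        rows.append(rid)
        cols.append(rid)
        vals.append(diag)

        # pressure gradient: cells L = face − ê_a, R = face
        cL = F.copy(); cL[:, a] -= 1
        cR = F
        rows.append(rid); cols.append(pid[cR[:, 0], cR[:, 1], cR[:, 2]])
        vals.append(np.full(len(F), 1.0 / h))
        rows.append(rid); cols.append(pid[cL[:, 0], cL[:, 1], cL[:, 2]])
        vals.append(np.full(len(F), -1.0 / h))

    # continuity rows (one per fluid cell), pinning one pressure/component
    C = np.argwhere(pid >= 0)
    crow = pid[C[:, 0], C[:, 1], C[:, 2]]
    pinned = np.zeros(len(C), dtype=bool)
    ccomp = comp[C[:, 0], C[:, 1], C[:, 2]]
    for c in range(1, n_comp + 1):
        first = np.nonzero(ccomp == c)[0][0]
        pinned[first] = True
        rows.append(np.array([crow[first]]))
        cols.append(np.array([crow[first]]))
        vals.append(np.array([1.0]))
    act = ~pinned
    for a, fs in enumerate(faces):
        for sgn, shift in ((-1.0, 0), (1.0, 1)):
            fc = C[act].copy()
            fc[:, a] += shift
            r = crow[act]
            fdof = fs.dof[fc[:, 0], fc[:, 1], fc[:, 2]]
            if fdof.any():
                rows.append(r[fdof])
                cols.append(dof_idx[a][fc[fdof, 0], fc[fdof, 1], fc[fdof, 2]])
                vals.append(np.full(int(fdof.sum()), sgn / h))
            vv = fs.value[fc[~fdof, 0], fc[~fdof, 1], fc[~fdof, 2]]
            np.add.at(b, r[~fdof], -sgn * vv / h)

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_tot, n_tot),
    )
    return A, b


def _interp_face_velocity(a, F, u_full):
    """Advecting velocity (3 components) interpolated at faces ``F`` of
    axis ``a`` from full staggered arrays."""
    out = []
    for d in range(3):
        if d == a:
            out.append(u_full[a][F[:, 0], F[:, 1], F[:, 2]])
            continue
        # average the 4 surrounding faces of axis d
        acc = np.zeros(len(F))
        for da in (0, -1):   # shift along axis a (cell L vs R)
            for dd in (0, 1):  # the two d-faces of that cell
                idx = F.copy()
                idx[:, a] += da
                idx[:, d] += dd
                acc += u_full[d][idx[:, 0], idx[:, 1], idx[:, 2]]
        out.append(acc / 4.0)
    return out


def _wall_speed(a, fs, nb, mw_pad, mw_vel):
    """Tangential wall speed (component a) at ghost faces, from the
    moving-wall mask (padded); zero for static walls."""
    sl_l, sl_r = _face_axes_slices(a, tuple(s - 2 for s in mw_pad.shape))
    mL = mw_pad[sl_l][nb[:, 0], nb[:, 1], nb[:, 2]]
    mR = mw_pad[sl_r][nb[:, 0], nb[:, 1], nb[:, 2]]
    return np.where(mL | mR, mw_vel[a], 0.0)


def max_divergence(sol: FlowSolution, domain: VoxelDomain) -> float:
    """Maximum |∇·u| over fluid cells, s⁻¹ (discrete mass-conservation
    check for the continuity equation)."""
    h = sol.spacing
    div = (
        (sol.ux[1:] - sol.ux[:-1])
        + (sol.uy[:, 1:] - sol.uy[:, :-1])
        + (sol.uz[:, :, 1:] - sol.uz[:, :, :-1])
    ) / h
    m = domain.fluid_mask
    if not m.any():
        return 0.0
    return float(np.abs(div[m]).max())


@dataclass
class WallShearField:
    """Wall shear stress sampled on solid-adjacent fluid faces.

    ``tau_raw`` is the one-sided estimate μ|u_t|/(h/2) per staircase face;
    ``tau_corrected`` rescales it by the local surface-normal obliquity
    (estimated from a smoothed solid-indicator gradient) so that stresses
    refer to the true, not staircase, surface area.  ``area_weights`` are
    the corresponding projected-area fractions; the area-weighted mean of
    the corrected stress is force-consistent on curved voxelized surfaces.
    """

    positions: np.ndarray  # (n, 3) face midpoints, m
    normals: np.ndarray    # (n, 3) outward face axis unit vectors
    tau_raw: np.ndarray
    tau_corrected: np.ndarray
    area_weights: np.ndarray

    def mean(self) -> float:
        return float(
            np.sum(self.tau_corrected * self.area_weights)
            / np.sum(self.area_weights)
        )

    def max(self) -> float:
        return float(self.tau_corrected.max())


def wall_shear_stress(
    sol: FlowSolution,
    domain: VoxelDomain,
    fluid: FluidProps,
    surface_labels: tuple[Label, ...] = (Label.WALL, Label.SCAFFOLD),
    smoothing_sigma: float = 1.0,
    moving_wall: tuple[np.ndarray, tuple[float, float, float]] | None = None,
) -> WallShearField:
    """Shear stress on fluid faces adjacent to the given solid labels.

    For moving walls pass the same ``moving_wall`` given to the solver so
    the shear is computed from the fluid velocity relative to the wall.
    """
    labels = domain.labels
    h = domain.spacing
    mu = fluid.dynamic_viscosity
    cx, cy, cz = sol.velocity_at_centers()
    solid = np.isin(labels, [int(l) for l in surface_labels]).astype(float)
    sm = ndi.gaussian_filter(solid, smoothing_sigma)
    grad = np.stack(np.gradient(sm, h), axis=0)

    pos, nrm, raw, corr, wts = [], [], [], [], []
    fluid_m = domain.fluid_mask
    for d, step in _DIRS:
        shifted = np.roll(solid.astype(bool), -np.array(step), axis=(0, 1, 2))
        # roll wraps; edges are solid-free fluid? fluid never touches edges
        m = fluid_m & shifted
        cells = np.argwhere(m)
        if len(cells) == 0:
            continue
        i, j, k = cells.T
        uc = np.stack([cx[i, j, k], cy[i, j, k], cz[i, j, k]], axis=1)
        e = np.array(step, dtype=float)
        sc = cells + np.array(step)
        if moving_wall is not None:
            mw_mask, mw_vel = moving_wall
            mov = mw_mask[sc[:, 0], sc[:, 1], sc[:, 2]]
            uc = uc - np.where(mov[:, None], np.asarray(mw_vel, float), 0.0)
        ut = uc - np.outer(uc @ e, e)
        tau = mu * np.linalg.norm(ut, axis=1) / (h / 2.0)
        g = 0.5 * (
            grad[:, i, j, k] + grad[:, sc[:, 0], sc[:, 1], sc[:, 2]]
        ).T
        gn = np.linalg.norm(g, axis=1)
        cosang = np.where(gn > 0, np.abs(g @ e) / np.maximum(gn, 1e-300), 1.0)
        cosang = np.clip(cosang, 0.2, 1.0)
        center = domain.origin + (cells + 0.5) * h + 0.5 * h * np.array(step)
        pos.append(center)
        nrm.append(np.tile(e, (len(cells), 1)))
        raw.append(tau)
        corr.append(tau / cosang)
        wts.append(cosang)
    if not pos:
        raise ValueError("no fluid faces adjacent to the requested labels")
    return WallShearField(
        positions=np.concatenate(pos),
        normals=np.concatenate(nrm),
        tau_raw=np.concatenate(raw),
        tau_corrected=np.concatenate(corr),
        area_weights=np.concatenate(wts),
    )
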