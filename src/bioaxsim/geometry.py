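"""Voxelized chamber and scaffold geometry.

The simulation domain is a labeled, isotropic, cell-centered voxel grid
(:class:`VoxelDomain`).  Labels partition the grid into fluid, chamber
wall, scaffold solid, the flat air–liquid interface at the fill height,
inlet/outlet port patches on the base, and symmetry planes (the cylindrical
chamber is normally simulated as one quadrant).

Two porous-scaffold generators are provided:

* ``sphere_subtraction`` — a random cluster of equal spheres is subtracted
  from a solid parallelepiped, mimicking fabricated bone-like scaffolds;
  the sphere count is tuned so the void fraction hits the target porosity.
* ``strut_lattice`` — a deterministic grid of intersecting orthogonal
  struts (the simplified geometry used in chamber-scale simulations),
  with strut widths chosen so the voxelized porosity hits the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Sequence

import numpy as np


class Label(IntEnum):
    """Per-voxel region label.  Every voxel carries exactly one."""

    FLUID = 1
    WALL = 2
    SCAFFOLD = 3  # scaffold solid
    INTERFACE = 4  # air–liquid interface (gas side)
    INLET = 5
    OUTLET = 6
    SYMMETRY = 7


SOLID_LABELS = (Label.WALL, Label.SCAFFOLD)


class ScaffoldVariant(str, Enum):
    sphere_subtraction = "sphere_subtraction"
    strut_lattice = "strut_lattice"


@dataclass(frozen=True)
class ScaffoldSpec:
    """Porous scaffold block specification (SI units, metres).

    ``pore_diameter`` is the subtracted-sphere diameter; ``pore_spacing``
    the nominal center-to-center distance (for the strut variant it is the
    strut pitch).  Overlapping pores are allowed by design — the random
    cluster is tuned only by its total porosity.
    """

    dims: tuple[float, float, float] = (10e-3, 10e-3, 3e-3)
    pore_diameter: float = 700e-6
    pore_spacing: float = 700e-6
    target_porosity: float = 0.525
    variant: ScaffoldVariant = ScaffoldVariant.sphere_subtraction
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("scaffold dimensions must be positive")
        if not 0.0 <= self.target_porosity <= 1.0:
            raise ValueError("target porosity must lie in [0, 1]")
        if self.pore_diameter <= 0 or self.pore_spacing <= 0:
            raise ValueError("pore dimensions must be positive")


@dataclass(frozen=True)
class ChamberSpec:
    """Cylindrical perfusion chamber (SI units)."""

    diameter: float = 0.08
    fill_volume: float = 110e-6  # m³ of medium in the vessel
    n_scaffolds: int = 12
    port_diameter: float = 1.6e-3
    quarter_symmetry: bool = True

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.fill_volume <= 0 or self.port_diameter <= 0:
            raise ValueError("chamber dimensions must be positive")
        if self.quarter_symmetry and self.n_scaffolds % 4 != 0:
            raise ValueError("quarter symmetry requires a multiple of 4 scaffolds")

    @property
    def fill_height(self) -> float:
        return self.fill_volume / (math.pi * (self.diameter / 2) ** 2)


@dataclass
class VoxelDomain:
    """Labeled structured grid with isotropic spacing.

    ``labels[i, j, k]`` is the :class:`Label` of the voxel whose center is
    ``origin + (i + ½, j + ½, k + ½)·spacing`` (right-handed axes, z
    vertical, 0-based indices).  Fluid voxels never touch the array
    boundary; the outermost layer always carries boundary labels.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        valid = np.isin(self.labels, [int(l) for l in Label])
        if not valid.all():
            raise ValueError("labels contain values outside the label set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.labels == int(Label.FLUID)

    @property
    def solid_mask(self) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in SOLID_LABELS])

    @property
    def fluid_volume(self) -> float:
        return float(self.fluid_mask.sum()) * self.spacing**3

    def cell_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def require_fluid(self) -> None:
        if not self.fluid_mask.any():
            raise ValueError("domain contains no fluid voxels")


# ---------------------------------------------------------------------------
# porosity

def measure_porosity(block: VoxelDomain, envelope: np.ndarray | None = None) -> float:
    """Void fraction of a scaffold block: fluid voxels / total voxels.

    ``envelope`` optionally restricts the count to a boolean sub-region
    (default: the whole block array, which for generator output is exactly
    the scaffold envelope).
    """
    if envelope is None:
        envelope = np.ones(block.shape, dtype=bool)
    total = int(envelope.sum())
    if total == 0:
        raise ValueError("empty envelope")
    fluid = int((block.fluid_mask & envelope).sum())
    return fluid / total


# ---------------------------------------------------------------------------
# sphere-subtraction scaffolds

def subtract_spheres(
    dims: Sequence[float],
    centers: np.ndarray,
    radius: float,
    spacing: float,
) -> VoxelDomain:
    """Voxelize a solid block minus a union of spheres (utility kernel)."""
    shape = tuple(max(1, round(d / spacing)) for d in dims)
    labels = np.full(shape, int(Label.SCAFFOLD), dtype=np.uint8)
    if len(centers):
        cover = _first_cover_index(shape, spacing, np.asarray(centers, float), radius)
        labels[cover < len(centers)] = int(Label.FLUID)
    return VoxelDomain(labels, spacing)


def _first_cover_index(shape, spacing, centers, radius) -> np.ndarray:
    """For each voxel, index of the first sphere in ``centers`` covering it
    (len(centers) if none).  Lets porosity-vs-count be read off in one pass."""
    K = len(centers)
    cover = np.full(shape, K, dtype=np.int32)
    axes = [(np.arange(n) + 0.5) * spacing for n in shape]
    r2 = radius * radius
    for k in range(K - 1, -1, -1):  # reverse order: later writes win = smaller k
        c = centers[k]
        lo = [max(0, int((c[a] - radius) / spacing - 1)) for a in range(3)]
        hi = [min(shape[a], int((c[a] + radius) / spacing + 2)) for a in range(3)]
        if any(lo[a] >= hi[a] for a in range(3)):
            continue
        dx = axes[0][lo[0]:hi[0]] - c[0]
        dy = axes[1][lo[1]:hi[1]] - c[1]
        dz = axes[2][lo[2]:hi[2]] - c[2]
        d2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        sub = cover[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[d2 < r2] = k
    return cover


def generate_sphere_subtracted_scaffold(
    spec: ScaffoldSpec,
    spacing: float | None = None,
    porosity_tol: float = 0.005,
) -> VoxelDomain:
    """Random-sphere-subtraction scaffold block tuned to the target porosity.

    Sphere centers are sampled uniformly inside the block (reproducibly from
    ``spec.seed``); the number of subtracted spheres is then chosen — porosity
    is monotone in the count — so the measured void fraction is within
    ``porosity_tol`` of the target.  Raises if the target is unreachable,
    reporting the closest achieved porosity.
    """
    if spec.variant is not ScaffoldVariant.sphere_subtraction:
        raise ValueError("spec variant must be sphere_subtraction")
    if spacing is None:
        spacing = min(spec.pore_diameter / 4.0, 0.175e-3)
    if spacing > spec.pore_diameter / 4.0 + 1e-12:
        raise ValueError("voxel spacing must be ≤ pore_diameter / 4")

    shape = tuple(max(1, round(d / spacing)) for d in spec.dims)
    if spec.target_porosity == 0.0:
        return VoxelDomain(np.full(shape, int(Label.SCAFFOLD), np.uint8), spacing)

    radius = spec.pore_diameter / 2.0
    block_vol = float(np.prod(spec.dims))
    sphere_vol = 4.0 / 3.0 * math.pi * radius**3
    # Boolean-model estimate of the count needed, with generous headroom.
    phi = min(spec.target_porosity, 0.999)
    k_est = -math.log(1.0 - phi) * block_vol / sphere_vol
    k_max = int(4 * k_est) + 64

    rng = np.random.default_rng(spec.seed)
    centers = rng.uniform(low=(0, 0, 0), high=spec.dims, size=(k_max, 3))
    cover = _first_cover_index(shape, spacing, centers, radius)

    n_total = int(np.prod(shape))
    covered_at = np.bincount(cover.ravel(), minlength=k_max + 1)[:k_max]
    cum = np.concatenate([[0], np.cumsum(covered_at)])  # voxels void using first k
    porosities = cum / n_total
    k_best = int(np.argmin(np.abs(porosities - spec.target_porosity)))
    achieved = porosities[k_best]
    if abs(achieved - spec.target_porosity) > porosity_tol:
        raise RuntimeError(
            f"target porosity {spec.target_porosity:.4f} unreachable; "
            f"closest achieved {achieved:.4f} with {k_best} spheres"
        )
    labels = np.full(shape, int(Label.SCAFFOLD), dtype=np.uint8)
    labels[cover < k_best] = int(Label.FLUID)
    return VoxelDomain(labels, spacing)


# ---------------------------------------------------------------------------
# strut-lattice scaffolds

def _best_column_counts(nx: int, ny: int, porosity: float) -> tuple[int, int]:
    """Integer solid-column counts (Sx, Sy) so that the separable lattice
    porosity (1 − Sx/nx)(1 − Sy/ny) best matches the target.

    Both directions must carry struts (the lattice is an intersecting
    grid); among near-optimal pairs the most symmetric one is preferred,
    so the per-direction width/pitch ratios stay close to 1 − √porosity.
    """
    if porosity >= 1.0:
        return (0, 0)
    best_key = None
    best = (1, 1)
    for sx in range(1, nx):
        rem = 1.0 - sx / nx
        if porosity / rem > 1.0:
            continue
        target_sy = ny * (1.0 - porosity / rem)
        for s in (math.floor(target_sy), math.ceil(target_sy)):
            if not 1 <= s < ny:
                continue
            p = rem * (1.0 - s / ny)
            err = abs(p - porosity)
            key = (int(err / 0.002), abs(sx - s), err)
            if best_key is None or key < best_key:
                best_key = key
                best = (sx, s)
    return best


def _strut_columns(n: int, n_struts: int, total_width: int) -> np.ndarray:
    """Boolean column mask: ``total_width`` solid columns distributed over
    ``n_struts`` evenly spaced struts.  Raises if struts would merge."""
    mask = np.zeros(n, dtype=bool)
    if total_width == 0:
        return mask
    base, extra = divmod(total_width, n_struts)
    widths = [base + (1 if i < extra else 0) for i in range(n_struts)]
    pitch = n / n_struts
    if max(widths) >= pitch:
        raise ValueError("strut width exceeds pitch; lattice would be solid")
    spans = []
    for i, w in enumerate(widths):
        c = (i + 0.5) * pitch
        start = int(round(c - w / 2.0))
        start = min(max(start, 0), n - w)
        spans.append((start, start + w))
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if e0 > s1:
            raise ValueError("strut width exceeds pitch; struts overlap")
    for s, e in spans:
        mask[s:e] = True
    return mask


def generate_strut_scaffold(
    spec: ScaffoldSpec,
    spacing: float | None = None,
    porosity_tol: float = 0.005,
) -> VoxelDomain:
    """Deterministic lattice of intersecting orthogonal struts.

    Vertical walls running along x and along y (extruded over the block
    height) intersect to form a periodic grid of rectangular channels.  For
    per-direction solid fractions ax, ay the porosity is (1−ax)(1−ay);
    integer column counts are chosen to match the target within tolerance,
    distributing any remainder across struts.
    """
    if spec.variant is not ScaffoldVariant.strut_lattice:
        raise ValueError("spec variant must be strut_lattice")
    if spacing is None:
        spacing = 0.125e-3
    shape = tuple(max(1, round(d / spacing)) for d in spec.dims)
    nx, ny, _ = shape
    sx, sy = _best_column_counts(nx, ny, spec.target_porosity)
    achieved = (1.0 - sx / nx) * (1.0 - sy / ny)
    if abs(achieved - spec.target_porosity) > porosity_tol:
        raise RuntimeError(
            f"target porosity {spec.target_porosity:.4f} unreachable on this "
            f"grid; closest achievable {achieved:.4f}"
        )
    n_struts_x = max(1, round(spec.dims[0] / spec.pore_spacing))
    n_struts_y = max(1, round(spec.dims[1] / spec.pore_spacing))
    cols_x = _strut_columns(nx, n_struts_x, sx)
    cols_y = _strut_columns(ny, n_struts_y, sy)
    solid2d = cols_x[:, None] | cols_y[None, :]
    labels = np.where(solid2d[:, :, None], int(Label.SCAFFOLD), int(Label.FLUID))
    labels = np.broadcast_to(labels, shape).astype(np.uint8)
    return VoxelDomain(labels.copy(), spacing)


# ---------------------------------------------------------------------------
# coarsening (embedding fine scaffold blocks on the chamber grid)

def coarsen_block(
    block: VoxelDomain, coarse_spacing: float, solid_threshold: float = 0.5
) -> VoxelDomain:
    """Resample a scaffold block onto a coarser grid by solid fraction.

    Each coarse voxel becomes scaffold solid when the fine-voxel solid
    fraction inside it reaches ``solid_threshold``.  Feature sizes below the
    coarse spacing are therefore homogenised — at chamber resolution a
    ~50 %-porous lattice collapses to a nearly solid block, which is the
    intended representation of an unresolved porous obstacle.
    """
    if coarse_spacing < block.spacing:
        raise ValueError("coarse spacing must be ≥ block spacing")
    dims = np.array(block.shape) * block.spacing
    cshape = tuple(max(1, round(d / coarse_spacing)) for d in dims)
    solid = block.solid_mask.astype(float)
    frac = np.zeros(cshape)
    cnt = np.zeros(cshape)
    idx = [
        np.minimum(
            ((np.arange(block.shape[a]) + 0.5) * block.spacing
             / coarse_spacing).astype(int),
            cshape[a] - 1,
        )
        for a in range(3)
    ]
    I, J, K = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    np.add.at(frac, (I, J, K), solid)
    np.add.at(cnt, (I, J, K), 1.0)
    frac = np.divide(frac, cnt, out=np.zeros_like(frac), where=cnt > 0)
    labels = np.where(frac >= solid_threshold, int(Label.SCAFFOLD), int(Label.FLUID))
    return VoxelDomain(labels.astype(np.uint8), coarse_spacing)


# ---------------------------------------------------------------------------
# chamber assembly

def build_chamber_domain(
    chamber: ChamberSpec,
    scaffold_blocks: Sequence[VoxelDomain] = (),
    resolution: float = 2e-3,
    *,
    inlet_azimuth_deg: float = 45.0,
    inlet_radius_frac: float = 0.9,
    ring_radius_frac: float = 0.6,
    stand_height: float = 6e-3,
) -> VoxelDomain:
    """Assemble the (quarter- or full-) cylinder chamber domain.

    The chamber shell and base are walls; the top fluid surface at the fill
    height carries air-interface labels; circular inlet (base periphery)
    and outlet (base center) port patches are labeled on the base; scaffold
    blocks are embedded at evenly spaced azimuths on one ring at the stand
    height.  The set of fluid columns is chosen as the cells nearest the
    cylinder axis whose count best matches the requested fill volume, so
    the voxelized fluid volume tracks ``fill_volume`` closely.

    ``scaffold_blocks`` are fine-resolution blocks; they are resampled onto
    the chamber grid.  One block may be passed for all positions.
    """
    h = resolution
    R = chamber.diameter / 2.0
    quarter = chamber.quarter_symmetry
    frac = 0.25 if quarter else 1.0
    nz_f = max(1, round(chamber.fill_height / h))
    target_area = chamber.fill_volume * frac / (nz_f * h)

    if quarter:
        n_side = math.ceil(R / h) + 2
        nx = ny = n_side
        cx = cy = -h  # origin so the symmetry planes are at x=0, y=0
    else:
        n_side = 2 * math.ceil(R / h) + 2
        nx = ny = n_side
        cx = cy = -n_side * h / 2.0
    nz = nz_f + 2
    origin = np.array([cx, cy, -h])

    xs = cx + (np.arange(nx) + 0.5) * h
    ys = cy + (np.arange(ny) + 0.5) * h
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    rr = np.hypot(XX, YY)
    interior = np.ones_like(rr, dtype=bool)
    if quarter:
        interior = (XX > 0) & (YY > 0)
    # pick the m interior columns nearest the axis to match the fill volume
    m = max(1, round(target_area / h**2))
    order = np.argsort(rr[interior].ravel(), kind="stable")
    cand = np.argwhere(interior)
    if m > len(order):
        raise ValueError("resolution too coarse for the requested chamber")
    disk = np.zeros_like(rr, dtype=bool)
    sel = cand[order[:m]]
    disk[sel[:, 0], sel[:, 1]] = True
    if rr[disk].max() > R + h:  # sanity: selected columns stay near radius R
        raise ValueError("fill volume inconsistent with chamber diameter")

    labels = np.full((nx, ny, nz), int(Label.WALL), dtype=np.uint8)
    labels[disk, 1:nz_f + 1] = int(Label.FLUID)
    labels[disk, nz_f + 1] = int(Label.INTERFACE)
    if quarter:
        labels[0, :, :] = int(Label.SYMMETRY)
        labels[:, 0, :] = int(Label.SYMMETRY)

    # ports on the base (k = 0), under fluid columns
    def _port(center_xy, label):
        px, py = center_xy
        d2 = (XX - px) ** 2 + (YY - py) ** 2
        patch = disk & (d2 < (chamber.port_diameter / 2.0) ** 2)
        if not patch.any():
            flat = np.where(disk.ravel(), d2.ravel(), np.inf)
            patch = np.zeros_like(disk)
            patch.ravel()[np.argmin(flat)] = True
        labels[patch, 0] = int(label)

    th = math.radians(inlet_azimuth_deg)
    r_in = inlet_radius_frac * R
    if quarter:
        _port((r_in * math.cos(th), r_in * math.sin(th)), Label.INLET)
        _port((0.0, 0.0), Label.OUTLET)
    else:
        for az in (45.0, 135.0, 225.0, 315.0):
            a = math.radians(az)
            _port((r_in * math.cos(a), r_in * math.sin(a)), Label.INLET)
        _port((0.0, 0.0), Label.OUTLET)

    dom = VoxelDomain(labels, h, origin)

    # scaffold placement on one ring
    n_here = chamber.n_scaffolds // 4 if quarter else chamber.n_scaffolds
    if n_here and scaffold_blocks:
        blocks = list(scaffold_blocks)
        if len(blocks) == 1:
            blocks = blocks * n_here
        if len(blocks) != n_here:
            raise ValueError(
                f"expected 1 or {n_here} scaffold blocks, got {len(blocks)}"
            )
        r_ring = ring_radius_frac * R
        span = 90.0 if quarter else 360.0
        for j, blk in enumerate(blocks):
            az = math.radians((j + 0.5) * span / n_here)
            _embed_scaffold(
                dom, blk, (r_ring * math.cos(az), r_ring * math.sin(az)),
                stand_height, nz_f,
            )
    return dom


def _embed_scaffold(dom, block, center_xy, z_bottom, nz_f) -> None:
    coarse = block if abs(block.spacing - dom.spacing) < 1e-12 else coarsen_block(
        block, dom.spacing
    )
    bx, by, bz = coarse.shape
    h = dom.spacing
    i0 = int(round((center_xy[0] - bx * h / 2.0 - dom.origin[0]) / h))
    j0 = int(round((center_xy[1] - by * h / 2.0 - dom.origin[1]) / h))
    k0 = int(round((z_bottom - dom.origin[2]) / h))
    solid = coarse.solid_mask
    sl = (slice(i0, i0 + bx), slice(j0, j0 + by), slice(k0, k0 + bz))
    if (
        i0 < 0 or j0 < 0 or k0 < 1
        or i0 + bx > dom.shape[0] or j0 + by > dom.shape[1]
        or k0 + bz > nz_f + 1
    ):
        raise ValueError("scaffold block extends outside the fluid region")
    target = dom.labels[sl]
    if np.any(solid & (target == int(Label.SCAFFOLD))):
        raise ValueError("scaffold blocks overlap")
    if np.any(solid & (target != int(Label.FLUID))):
        raise ValueError("scaffold block extends outside the fluid region")
    target[solid] = int(Label.SCAFFOLD)
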