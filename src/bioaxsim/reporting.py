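"""Field summaries and slice extraction for reporting.

Concentrations are reported in µM (1 mol·m⁻³ = 1000 µM).  Region
definitions: the interface region is the set of fluid cells within two
voxels of air-interface labels; the near-wall region within two voxels of
chamber-wall labels; scaffold-surface cells are fluid cells face-adjacent
to scaffold solid, with the "external" subset restricted to cells outside
each scaffold's bounding box interior (i.e. on the envelope exposed to
bulk flow); the far-from-scaffold region is fluid farther than a given
distance from any scaffold voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from . import units
from .geometry import Label, VoxelDomain


@dataclass
class SummaryStats:
    """Volume-weighted summary of a concentration field, in µM.

    Region values are ``None`` when the region is empty (absent, not zero).
    """

    mean_uM: float
    min_uM: float
    max_uM: float
    interface_mean_uM: float | None = None
    near_wall_min_uM: float | None = None
    scaffold_surface_mean_uM: float | None = None
    external_scaffold_surface_mean_uM: float | None = None
    far_from_scaffold_mean_uM: float | None = None
    region_cells: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "mean_uM", "min_uM", "max_uM", "interface_mean_uM",
                "near_wall_min_uM", "scaffold_surface_mean_uM",
                "external_scaffold_surface_mean_uM",
                "far_from_scaffold_mean_uM",
            )
        }


_STRUCT = ndi.generate_binary_structure(3, 1)  # face connectivity


def _shell(mask: np.ndarray, fluid: np.ndarray, width: int) -> np.ndarray:
    if not mask.any():
        return np.zeros_like(mask)
    return ndi.binary_dilation(mask, _STRUCT, iterations=width) & fluid


def summarize_field(
    c: np.ndarray,
    domain: VoxelDomain,
    shell_width: int = 2,
    far_distance: float = 5e-3,
) -> SummaryStats:
    """Summarize a cell-centered concentration field (mol·m⁻³) over the
    fluid region and the standard report regions."""
    fluid = domain.fluid_mask
    if not fluid.any():
        raise ValueError("domain has no fluid cells")
    vals = c[fluid]
    if np.isnan(vals).any():
        raise ValueError("concentration undefined on some fluid cells")
    to_um = units.mol_m3_to_um
    stats = SummaryStats(
        mean_uM=float(to_um(vals.mean())),
        min_uM=float(to_um(vals.min())),
        max_uM=float(to_um(vals.max())),
    )

    iface = _shell(domain.mask(Label.INTERFACE), fluid, shell_width)
    if iface.any():
        stats.interface_mean_uM = float(to_um(c[iface].mean()))
        stats.region_cells["interface"] = int(iface.sum())

    wall = _shell(domain.mask(Label.WALL), fluid, shell_width)
    if wall.any():
        stats.near_wall_min_uM = float(to_um(c[wall].min()))
        stats.region_cells["near_wall"] = int(wall.sum())

    scaf = domain.mask(Label.SCAFFOLD)
    if scaf.any():
        surf = _shell(scaf, fluid, 1)
        if surf.any():
            stats.scaffold_surface_mean_uM = float(to_um(c[surf].mean()))
            stats.region_cells["scaffold_surface"] = int(surf.sum())
            ext = surf & ~_interior_of_boxes(scaf)
            if ext.any():
                stats.external_scaffold_surface_mean_uM = float(
                    to_um(c[ext].mean())
                )
                stats.region_cells["external_scaffold_surface"] = int(ext.sum())
        dist = ndi.distance_transform_edt(~scaf, sampling=domain.spacing)
        far = fluid & (dist > far_distance)
        if far.any():
            stats.far_from_scaffold_mean_uM = float(to_um(c[far].mean()))
            stats.region_cells["far_from_scaffold"] = int(far.sum())
    return stats


def _interior_of_boxes(scaffold_mask: np.ndarray) -> np.ndarray:
    """Open interior of each connected scaffold's bounding box (cells in
    here are pore space, not envelope surface)."""
    labeled, n = ndi.label(scaffold_mask, _STRUCT)
    interior = np.zeros_like(scaffold_mask)
    for sl in ndi.find_objects(labeled):
        if sl is None:
            continue
        inner = tuple(
            slice(s.start + 1, max(s.start + 1, s.stop - 1)) for s in sl
        )
        interior[inner] = True
    return interior


def slice_extract(
    field_values: np.ndarray,
    domain: VoxelDomain,
    axis: int,
    position: float,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Extract the cell-centered 2-D slice nearest ``position`` (m) along
    ``axis``.  Returns the slice and the in-plane center coordinates."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    lo = domain.origin[axis]
    hi = lo + domain.shape[axis] * domain.spacing
    if not lo <= position < hi:
        raise ValueError(
            f"plane position {position:g} m outside domain [{lo:g}, {hi:g})"
        )
    idx = int((position - lo) / domain.spacing)
    sl = [slice(None)] * 3
    sl[axis] = idx
    other = [a for a in range(3) if a != axis]
    return field_values[tuple(sl)], tuple(
        domain.cell_centers(a) for a in other
    )


def region_partition_mean(
    c: np.ndarray, masks: list[np.ndarray]
) -> tuple[float, float]:
    """Volume-weighted mean computed directly and via a partition of
    region means (both returned; equal for any exact partition)."""
    union = np.zeros_like(masks[0])
    total = 0.0
    count = 0
    for m in masks:
        if (union & m).any():
            raise ValueError("masks must be disjoint")
        union |= m
        total += float(c[m].sum())
        count += int(m.sum())
    direct = float(c[union].mean())
    return direct, total / count
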