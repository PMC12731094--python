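"""Plain-text exports: legacy-VTK image data, ASCII STL, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import VoxelDomain


def write_vtk_image(
    path, domain: VoxelDomain, fields: dict[str, np.ndarray] | None = None
) -> None:
    """Write the domain labels (and optional cell fields) as legacy-VTK
    STRUCTURED_POINTS ASCII, readable by ParaView and meshio."""
    fields = fields or {}
    nx, ny, nz = domain.shape
    h = domain.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        "bioaxsim voxel domain",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {domain.origin[0]:g} {domain.origin[1]:g} {domain.origin[2]:g}",
        f"SPACING {h:g} {h:g} {h:g}",
        f"CELL_DATA {nx * ny * nz}",
        "SCALARS label int 1",
        "LOOKUP_TABLE default",
    ]
    order = domain.labels.transpose(2, 1, 0).ravel()  # VTK is x-fastest
    lines.extend(" ".join(map(str, row)) for row in order.reshape(-1, nx))
    for name, arr in fields.items():
        if arr.shape != domain.shape:
            raise ValueError(f"field {name!r} shape mismatch")
        vals = np.nan_to_num(arr, nan=0.0).transpose(2, 1, 0).ravel()
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(
            " ".join(f"{v:.6g}" for v in row) for row in vals.reshape(-1, nx)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def scaffold_to_stl(block: VoxelDomain, path) -> None:
    """Export the scaffold solid surface as ASCII STL (marching cubes)."""
    from skimage.measure import marching_cubes

    solid = np.pad(block.solid_mask.astype(float), 1)
    verts, faces, _, _ = marching_cubes(solid, level=0.5)
    verts = (verts - 1.0) * block.spacing + block.origin
    write_stl_ascii(path, verts, faces)


def write_stl_ascii(path, verts: np.ndarray, faces: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("solid bioaxsim\n")
        for tri in faces:
            a, b, c = verts[tri]
            n = np.cross(b - a, c - a)
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            fh.write(f"facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
            fh.write(" outer loop\n")
            for v in (a, b, c):
                fh.write(f"  vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid bioaxsim\n")
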