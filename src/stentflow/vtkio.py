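"""Minimal legacy-ASCII VTK writers for inspection output.

Only the two layouts the package emits are supported: STRUCTURED_POINTS
(voxel label / scalar fields) and POLYDATA polylines (stent wires). The
legacy ASCII format is used so the files stay text and need no VTK library.
"""

from __future__ import annotations

import numpy as np


def write_structured_points(path, array: np.ndarray, spacing: float,
                            origin=(0.0, 0.0, 0.0), name: str = "field") -> None:
    """Write a 3D scalar array (index order [ix, iy, iz]) as legacy VTK."""
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValueError("expected a 3D array")
    nx, ny, nz = arr.shape
    flat = arr.transpose(2, 1, 0).ravel()  # VTK is x-fastest
    is_int = np.issubdtype(arr.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentflow field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing} {spacing} {spacing}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} {'int' if is_int else 'float'} 1\n")
        fh.write("LOOKUP_TABLE default\n")
        if is_int:
            fh.write("\n".join(str(int(v)) for v in flat))
        else:
            fh.write("\n".join(f"{v:.6g}" for v in flat))
        fh.write("\n")


def write_polylines(path, points: np.ndarray, lines: list) -> None:
    """Write polylines (e.g. stent wires) as legacy VTK POLYDATA.

    ``lines`` is a list of index sequences into ``points``.
    """
    pts = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentflow wires\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for line in lines:
            fh.write(" ".join([str(len(line))] + [str(int(i)) for i in line]))
            fh.write("\n")
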