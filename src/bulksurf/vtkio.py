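"""Legacy-VTK ASCII and CSV output (plus a minimal reader for restarts).

Snapshots are written as VTK unstructured grids: triangle cells for the bulk
mesh, line cells for the boundary loops (tagged by loop id in cell data), and
point-data arrays for nodal fields.  The format is the plain-text legacy
variant so snapshots stay human-readable and diff-able.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import TriMesh


def write_vtk(path, mesh: TriMesh, point_data: dict[str, np.ndarray] | None = None,
              include_loops: bool = True) -> None:
    path = Path(path)
    pts = mesh.phys_coords
    tris = mesh.triangles
    loops = mesh.boundary_loops if include_loops else []
    n_line_cells = sum(len(l) for l in loops)
    lines = []
    lines.append("# vtk DataFile Version 3.0")
    lines.append("bulksurf snapshot")
    lines.append("ASCII")
    lines.append("DATASET UNSTRUCTURED_GRID")
    lines.append(f"POINTS {len(pts)} double")
    for p in pts:
        lines.append(f"{p[0]:.17g} {p[1]:.17g} 0")
    n_cells = len(tris) + n_line_cells
    size = 4 * len(tris) + 3 * n_line_cells
    lines.append(f"CELLS {n_cells} {size}")
    for t in tris:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    for loop in loops:
        for i, j in zip(loop, np.roll(loop, -1)):
            lines.append(f"2 {i} {j}")
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["5"] * len(tris))          # VTK_TRIANGLE
    lines.extend(["3"] * n_line_cells)       # VTK_LINE
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS loop_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(["-1"] * len(tris))
    for k, loop in enumerate(loops):
        lines.extend([str(k)] * len(loop))
    if point_data:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.17g}" for v in arr)
    path.write_text("\n".join(lines) + "\n")


def read_vtk_mesh(path) -> TriMesh:
    """Read back a mesh written by :func:`write_vtk` (triangles + loops)."""
    tokens = Path(path).read_text().split("\n")
    it = iter(range(len(tokens)))
    pts = None
    tris = []
    line_cells = []
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = np.array([[float(v) for v in tokens[i + 1 + k].split()[:2]]
                            for k in range(n)])
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            for k in range(n):
                parts = [int(v) for v in tokens[i + 1 + k].split()]
                if parts[0] == 3:
                    tris.append(parts[1:])
                elif parts[0] == 2:
                    line_cells.append(parts[1:])
            i += n
        i += 1
    if pts is None or not tris:
        raise ValueError(f"{path} does not contain a triangulated mesh")
    # reconstruct loops from the line cells (successor map)
    loops = []
    succ = dict(line_cells)
    seen = set()
    for start in succ:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        nxt = succ[start]
        while nxt != start:
            loop.append(nxt)
            seen.add(nxt)
            nxt = succ[nxt]
        loops.append(np.asarray(loop))
    pts = np.asarray(pts)
    return TriMesh(pts.copy(), pts.copy(), np.asarray(tris), loops)


def write_curve_csv(path, curve_coords: np.ndarray, columns: dict[str, np.ndarray]) -> None:
    """CSV snapshot of the boundary curve (index, x, y, extra columns)."""
    import pandas as pd

    df = pd.DataFrame({"index": np.arange(len(curve_coords)),
                       "x": curve_coords[:, 0], "y": curve_coords[:, 1]})
    for k, v in columns.items():
        df[k] = v
    df.to_csv(path, index=False)
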