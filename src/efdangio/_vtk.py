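"""Minimal legacy ASCII VTK writers (polydata only; used for glyphs and polylines)."""

from __future__ import annotations

import numpy as np


def write_polydata(
    path,
    points,
    polygons=None,
    lines=None,
    cell_scalars=None,
    cell_scalar_name="scalar",
    point_scalars=None,
    point_scalar_name="scalar",
):
    points = np.asarray(points, dtype=float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nefdangio export\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        n_cells = 0
        if polygons is not None:
            polygons = np.asarray(polygons, dtype=int)
            n_cells = len(polygons)
            fh.write(f"POLYGONS {len(polygons)} {polygons.size + len(polygons)}\n")
            for f in polygons:
                fh.write(f"{len(f)} " + " ".join(str(i) for i in f) + "\n")
        if lines is not None:
            lines = [np.asarray(l, dtype=int) for l in lines]
            n_cells = len(lines)
            total = sum(len(l) + 1 for l in lines)
            fh.write(f"LINES {len(lines)} {total}\n")
            for l in lines:
                fh.write(f"{len(l)} " + " ".join(str(i) for i in l) + "\n")
        if cell_scalars is not None:
            cell_scalars = np.asarray(cell_scalars, dtype=float)
            fh.write(f"CELL_DATA {n_cells}\n")
            fh.write(f"SCALARS {cell_scalar_name} float 1\nLOOKUP_TABLE default\n")
            for v in cell_scalars:
                fh.write(f"{v:.9g}\n")
        if point_scalars is not None:
            point_scalars = np.asarray(point_scalars, dtype=float)
            fh.write(f"POINT_DATA {len(points)}\n")
            fh.write(f"SCALARS {point_scalar_name} float 1\nLOOKUP_TABLE default\n")
            for v in point_scalars:
                fh.write(f"{v:.9g}\n")


def write_rectilinear_grid(path, x_edges, y_edges, z_edges, cell_data=None):
    """cell_data: mapping name -> flat array ordered x-minor (ix + nx*(iy + ny*iz))."""
    import numpy as np

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nefdangio export\nASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {len(x_edges)} {len(y_edges)} {len(z_edges)}\n")
        for name, e in (("X", x_edges), ("Y", y_edges), ("Z", z_edges)):
            fh.write(f"{name}_COORDINATES {len(e)} float\n")
            fh.write(" ".join(f"{v:.9g}" for v in e) + "\n")
        if cell_data:
            n = (len(x_edges) - 1) * (len(y_edges) - 1) * (len(z_edges) - 1)
            fh.write(f"CELL_DATA {n}\n")
            for name, values in cell_data.items():
                values = np.asarray(values, dtype=float)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in values:
                    fh.write(f"{v:.9g}\n")
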