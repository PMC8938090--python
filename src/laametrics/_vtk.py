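"""Minimal legacy ASCII VTK polydata reader/writer.

Supports the subset needed here: POINTS, POLYGONS (triangles), and named
scalar POINT_DATA arrays. Files produced by common mesh tools in legacy
ASCII mode round-trip through this module.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_vtk_polydata", "write_vtk_polydata"]


def read_vtk_polydata(path):
    """Read a legacy ASCII VTK polydata file.

    Returns (vertices (n,3) float array, faces (m,3) int array,
    point_data dict of name -> (n,) array).
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))
    # locate sections by keyword scan; legacy header is free-form enough
    # that token-level parsing is the robust option
    upper = [t.upper() for t in tokens]
    if "POLYDATA" not in upper:
        raise ValueError(f"{path}: not a VTK POLYDATA file")
    verts = None
    faces = None
    point_data: dict[str, np.ndarray] = {}
    i = 0
    n_points = 0
    while i < len(tokens):
        tok = upper[i]
        if tok == "POINTS":
            n_points = int(tokens[i + 1])
            data = np.array(tokens[i + 3 : i + 3 + 3 * n_points], dtype=float)
            verts = data.reshape(n_points, 3)
            i += 3 + 3 * n_points
        elif tok == "POLYGONS":
            n_polys = int(tokens[i + 1])
            size = int(tokens[i + 2])
            flat = np.array(tokens[i + 3 : i + 3 + size], dtype=int)
            faces_list = []
            j = 0
            for _ in range(n_polys):
                k = flat[j]
                poly = flat[j + 1 : j + 1 + k]
                if k == 3:
                    faces_list.append(poly)
                else:  # fan-triangulate larger polygons
                    for a in range(1, k - 1):
                        faces_list.append([poly[0], poly[a], poly[a + 1]])
                j += k + 1
            faces = np.array(faces_list, dtype=int)
            i += 3 + size
        elif tok == "SCALARS":
            name = tokens[i + 1]
            # skip LOOKUP_TABLE line (two tokens) if present
            j = i + 4
            if upper[j] == "LOOKUP_TABLE":
                j += 2
            point_data[name] = np.array(tokens[j : j + n_points], dtype=float)
            i = j + n_points
        else:
            i += 1
    if verts is None:
        raise ValueError(f"{path}: no POINTS section found")
    if faces is None:
        faces = np.zeros((0, 3), dtype=int)
    return verts, faces, point_data


def write_vtk_polydata(path, vertices, faces, point_data=None):
    """Write vertices/triangles (+ optional per-vertex scalars) as legacy ASCII."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("laametrics surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for v in vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(vertices)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in arr:
                    fh.write(f"{float(x):.9g}\n")
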