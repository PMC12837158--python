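"""Readers and writers for surfaces and centerlines.

STL (binary and ASCII) and PLY go through :mod:`trimesh`.  A minimal
legacy ASCII VTK POLYDATA reader/writer is provided for interoperability
with vascular-modeling toolchains; it covers triangulated ``POLYGONS``
surfaces and ``LINES`` polylines, which is all this pipeline exchanges.
Centerlines are also accepted as plain CSV with x,y,z columns.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import trimesh

from .geometry import GeometryError, SurfaceMesh


def load_mesh(path: str) -> SurfaceMesh:
    """Load a surface mesh from STL, PLY or legacy ASCII VTK polydata."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        verts, polys, _ = _read_vtk(path)
        if polys is None:
            raise GeometryError(f"{path}: VTK file contains no POLYGONS")
        return SurfaceMesh(verts, polys)
    # default processing merges the duplicated vertices STL stores per facet
    tm = trimesh.load(path, force="mesh")
    return SurfaceMesh.from_trimesh(tm)


def save_mesh(mesh: SurfaceMesh, path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        _write_vtk_polydata(path, mesh.vertices, polygons=mesh.faces)
        return
    mesh.to_trimesh().export(path)


def load_centerline_points(path: str) -> np.ndarray:
    """Ordered 3-D points from a CSV (x,y,z per row, optional header) or VTK LINES."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        verts, _, lines = _read_vtk(path)
        if lines is None:
            raise GeometryError(f"{path}: VTK file contains no LINES")
        return verts[lines]
    try:
        data = np.loadtxt(path, delimiter=",")
    except ValueError:
        data = np.loadtxt(path, delimiter=",", skiprows=1)
    return np.asarray(data, dtype=float).reshape(-1, 3)


def save_centerline_points(points: Sequence[Sequence[float]], path: str) -> None:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        _write_vtk_polydata(path, points, line=np.arange(len(points)))
        return
    np.savetxt(path, points, delimiter=",", header="x,y,z", comments="")


def _read_vtk(path: str):
    """Parse a legacy ASCII VTK POLYDATA file (POINTS + POLYGONS/LINES)."""
    with open(path) as fh:
        tokens = fh.read().split()
    tl = [t.upper() for t in tokens]
    if "POLYDATA" not in tl:
        raise GeometryError(f"{path}: not a VTK POLYDATA file")
    try:
        ip = tl.index("POINTS")
        n_pts = int(tokens[ip + 1])
        start = ip + 3
        verts = np.array(tokens[start : start + 3 * n_pts], dtype=float).reshape(-1, 3)
    except (ValueError, IndexError) as exc:
        raise GeometryError(f"{path}: malformed VTK POINTS block") from exc

    def _read_cells(keyword):
        if keyword not in tl:
            return None
        ic = tl.index(keyword)
        n_cells, total = int(tokens[ic + 1]), int(tokens[ic + 2])
        flat = np.array(tokens[ic + 3 : ic + 3 + total], dtype=int)
        cells, pos = [], 0
        for _ in range(n_cells):
            k = flat[pos]
            cells.append(flat[pos + 1 : pos + 1 + k])
            pos += 1 + k
        return cells

    polys = _read_cells("POLYGONS")
    if polys is not None:
        tri = []
        for cell in polys:
            for j in range(1, len(cell) - 1):  # fan-triangulate
                tri.append([cell[0], cell[j], cell[j + 1]])
        polys = np.asarray(tri, dtype=np.int64)
    lines = _read_cells("LINES")
    if lines is not None:
        lines = np.concatenate(lines)
    return verts, polys, lines


def _write_vtk_polydata(path, verts, polygons=None, line=None):
    verts = np.asarray(verts, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\neritwin surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} float\n")
        for p in verts:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        if polygons is not None:
            polygons = np.asarray(polygons, dtype=int)
            fh.write(f"POLYGONS {len(polygons)} {4 * len(polygons)}\n")
            for f in polygons:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if line is not None:
            line = np.asarray(line, dtype=int).ravel()
            fh.write(f"LINES 1 {len(line) + 1}\n")
            fh.write(str(len(line)) + " " + " ".join(str(i) for i in line) + "\n")
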