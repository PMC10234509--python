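"""Legacy-ASCII VTK unstructured-grid reader/writer.

Covers the subset this package needs: tetrahedral cells, point-data and
cell-data scalars/vectors (displacements, fiber vectors, von Mises
stress), and named node/facet sets.  Sets are stored twice: as 0/1 masks
inside the VTK file (so they render in standard viewers) and verbatim in
a JSON sidecar ``<file>.sets.json`` that preserves facet connectivity for
lossless round-trips.

Floats are written with 17 significant digits, so a write/read round
trip reproduces fields bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .mesh import Mesh

__all__ = ["write_mesh", "read_mesh", "sidecar_path"]

_FMT = "%.17g"


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".sets.json")


def _write_array(fh, arr: np.ndarray) -> None:
    np.savetxt(fh, np.atleast_2d(arr), fmt=_FMT)


def write_mesh(mesh: Mesh, path: str | Path,
               point_data: dict | None = None,
               cell_data: dict | None = None) -> Path:
    """Write a mesh (plus optional fields) as legacy ASCII VTK.

    ``point_data`` and ``cell_data`` map names to (n,) scalars or (n, 3)
    vectors.  The element fiber field, if present, is written as the cell
    vector field ``fibers``.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if mesh.fibers is not None and "fibers" not in cell_data:
        cell_data["fibers"] = mesh.fibers
    for name, idx in mesh.node_sets.items():
        mask = np.zeros(mesh.n_nodes)
        mask[np.asarray(idx, dtype=int)] = 1.0
        point_data.setdefault(f"nset_{name}", mask)

    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("myofe unstructured grid\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        _write_array(fh, mesh.nodes)
        m = mesh.n_elements
        fh.write(f"CELLS {m} {5 * m}\n")
        cells = np.hstack([np.full((m, 1), 4, dtype=np.int64), mesh.tets])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10, dtype=np.int64), fmt="%d")

        def emit(section: str, count: int, data: dict) -> None:
            if not data:
                return
            fh.write(f"{section} {count}\n")
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape == (count,):
                    fh.write(f"SCALARS {name} double 1\n")
                    fh.write("LOOKUP_TABLE default\n")
                    _write_array(fh, arr[:, None])
                elif arr.shape == (count, 3):
                    fh.write(f"VECTORS {name} double\n")
                    _write_array(fh, arr)
                else:
                    raise ConfigurationError(
                        f"field {name!r} has shape {arr.shape}, expected "
                        f"({count},) or ({count}, 3)")

        emit("CELL_DATA", m, cell_data)
        emit("POINT_DATA", mesh.n_nodes, point_data)

    sets = {
        "node_sets": {k: np.asarray(v, dtype=int).tolist()
                      for k, v in mesh.node_sets.items()},
        "facet_sets": {k: np.asarray(v, dtype=int).tolist()
                       for k, v in mesh.facet_sets.items()},
    }
    sidecar_path(path).write_text(json.dumps(sets))
    return path


def read_mesh(path: str | Path):
    """Read a legacy ASCII VTK tet mesh written by :func:`write_mesh`.

    Returns ``(mesh, point_data, cell_data)``; the ``fibers`` cell vector
    field, if present, is attached to the mesh.
    """
    path = Path(path)
    tokens = path.read_text().split("\n")
    i = 0

    def line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        if i >= len(tokens):
            return None
        out = tokens[i].strip()
        i += 1
        return out

    def read_floats(rows: int, cols: int) -> np.ndarray:
        nonlocal i
        vals: list = []
        need = rows * cols
        while len(vals) < need:
            vals.extend(float(x) for x in tokens[i].split())
            i += 1
        return np.array(vals).reshape(rows, cols)

    header = line()
    if header is None or not header.startswith("# vtk"):
        raise ConfigurationError(f"{path} is not a legacy VTK file")
    line()  # title
    if line() != "ASCII":
        raise ConfigurationError("only ASCII VTK is supported")
    if line() != "DATASET UNSTRUCTURED_GRID":
        raise ConfigurationError("only UNSTRUCTURED_GRID is supported")

    nodes = tets = None
    point_data: dict = {}
    cell_data: dict = {}
    section = None
    while True:
        ln = line()
        if ln is None:
            break
        parts = ln.split()
        kw = parts[0].upper()
        if kw == "POINTS":
            n = int(parts[1])
            nodes = read_floats(n, 3)
        elif kw == "CELLS":
            m = int(parts[1])
            raw = read_floats(m, 5).astype(np.int64)
            if np.any(raw[:, 0] != 4):
                raise ConfigurationError("only tetrahedral cells supported")
            tets = raw[:, 1:]
        elif kw == "CELL_TYPES":
            read_floats(int(parts[1]), 1)
        elif kw == "CELL_DATA":
            section = cell_data
            count = int(parts[1])
        elif kw == "POINT_DATA":
            section = point_data
            count = int(parts[1])
        elif kw == "SCALARS":
            name = parts[1]
            line()  # LOOKUP_TABLE
            section[name] = read_floats(count, 1).ravel()
        elif kw == "VECTORS":
            section[parts[1]] = read_floats(count, 3)
        else:
            raise ConfigurationError(f"unsupported VTK keyword {kw!r}")

    if nodes is None or tets is None:
        raise ConfigurationError(f"{path} lacks POINTS/CELLS sections")
    node_sets: dict = {}
    facet_sets: dict = {}
    side = sidecar_path(path)
    if side.exists():
        sets = json.loads(side.read_text())
        node_sets = {k: np.asarray(v, dtype=np.int64)
                     for k, v in sets.get("node_sets", {}).items()}
        facet_sets = {k: np.asarray(v, dtype=np.int64).reshape(-1, 3)
                      for k, v in sets.get("facet_sets", {}).items()}
    fibers = cell_data.get("fibers")
    mesh = Mesh(nodes=nodes, tets=tets, node_sets=node_sets,
                facet_sets=facet_sets, fibers=fibers)
    return mesh, point_data, cell_data
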