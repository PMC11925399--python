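"""Mesh and snapshot I/O.

Meshes are written/read as ASCII PLY or legacy ASCII VTK polydata
(polygonal faces, no triangulation).  Full simulation snapshots use a
lossless JSON container holding positions, connectivity, per-cell nematic
angles, morphogen counts, tangent frames and parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from nemashell.shell import CellularShell, compute_geometry
from nemashell.nematic import NematicField
from nemashell.morphogen import MorphogenField, MorphogenParams


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------


def write_ply(path, shell: CellularShell):
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {shell.n_vertices}",
        "property float x", "property float y", "property float z",
        f"element face {shell.n_cells}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in shell.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for c in shell.cells:
        lines.append(f"{len(c)} " + " ".join(str(int(x)) for x in c))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply(path) -> CellularShell:
    toks = Path(path).read_text().split("\n")
    it = iter(toks)
    n_vert = n_face = None
    for line in it:
        if line.startswith("element vertex"):
            n_vert = int(line.split()[-1])
        elif line.startswith("element face"):
            n_face = int(line.split()[-1])
        elif line.strip() == "end_header":
            break
    verts = np.array([[float(x) for x in next(it).split()[:3]] for _ in range(n_vert)])
    cells = []
    for _ in range(n_face):
        parts = next(it).split()
        cells.append([int(x) for x in parts[1:1 + int(parts[0])]])
    return CellularShell(verts, cells)


# ---------------------------------------------------------------------------
# legacy VTK polydata
# ---------------------------------------------------------------------------


def write_vtk(path, shell: CellularShell, cell_data: dict | None = None):
    lines = ["# vtk DataFile Version 3.0", "nemashell surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {shell.n_vertices} float"]
    for v in shell.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    size = sum(len(c) + 1 for c in shell.cells)
    lines.append(f"POLYGONS {shell.n_cells} {size}")
    for c in shell.cells:
        lines.append(f"{len(c)} " + " ".join(str(int(x)) for x in c))
    if cell_data:
        lines.append(f"CELL_DATA {shell.n_cells}")
        for name, values in cell_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(x):.9g}" for x in values)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON snapshot container
# ---------------------------------------------------------------------------


def save_snapshot(path, shell: CellularShell, nem: NematicField | None = None,
                  mor: MorphogenField | None = None, geom=None,
                  time: float = 0.0, extra: dict | None = None):
    if geom is None:
        geom = compute_geometry(shell)
    doc = {
        "format": "nemashell-snapshot-1",
        "time": time,
        "vertices": shell.vertices.tolist(),
        "cells": [c.tolist() for c in shell.cells],
        "frames_e1": geom.e1.tolist(),
    }
    if nem is not None:
        doc["nematic"] = {"q": nem.q.tolist(), "tau_q": nem.tau_q,
                          "alpha": nem.alpha}
    if mor is not None:
        doc["morphogen"] = {"N": mor.N.tolist(), "A_ref": mor.A_ref.tolist(),
                            "params": asdict(mor.params)}
    if extra:
        doc["extra"] = extra
    Path(path).write_text(json.dumps(doc))


def load_snapshot(path):
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "nemashell-snapshot-1":
        raise ValueError("not a nemashell snapshot file")
    shell = CellularShell(np.array(doc["vertices"]), doc["cells"])
    geom = compute_geometry(shell)
    e1 = np.array(doc["frames_e1"])
    # re-orthonormalize stored frames against current normals
    e1 = e1 - np.sum(e1 * geom.normals, axis=1, keepdims=True) * geom.normals
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    geom.e1 = e1
    geom.e2 = np.cross(geom.normals, e1)
    nem = mor = None
    if "nematic" in doc:
        d = doc["nematic"]
        nem = NematicField(np.array(d["q"]), d["tau_q"], d["alpha"])
    if "morphogen" in doc:
        d = doc["morphogen"]
        mor = MorphogenField(np.array(d["N"]), np.array(d["A_ref"]),
                             MorphogenParams(**d["params"]))
    return shell, geom, nem, mor, doc.get("time", 0.0), doc.get("extra")
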