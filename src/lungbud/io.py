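"""Plain-text artifact writers: Gmsh MSH meshes, VTU field snapshots,
CSV tables and JSON provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .mesh import Mesh

__all__ = ["write_msh", "write_vtu", "write_report_json", "write_provenance"]


def write_msh(mesh: Mesh, path) -> None:
    """Write the labelled mesh in Gmsh MSH 2.2 ASCII format.

    Subdomain labels are stored as the elements' physical tags.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.points, start=1):
            fh.write(f"{i} {x:.16g} {y:.16g} 0\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for e, (tri, lab) in enumerate(zip(mesh.tris, mesh.labels), start=1):
            a, b, c = (int(v) + 1 for v in tri)
            fh.write(f"{e} 2 2 {int(lab)} {int(lab)} {a} {b} {c}\n")
        fh.write("$EndElements\n")


def read_msh(path):
    """Read back a mesh written by :func:`write_msh`.

    Returns ``(points, tris, labels)`` (the parametric metadata is not
    part of the interchange format).
    """
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    points, tris, labels = [], [], []
    for line in it:
        if line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                _, x, y, _ = next(it).split()
                points.append((float(x), float(y)))
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                ntags = int(parts[2])
                labels.append(int(parts[3]))
                tris.append([int(v) - 1 for v in parts[3 + ntags:]])
    return np.asarray(points), np.asarray(tris), np.asarray(labels)


def write_vtu(mesh: Mesh, fields: dict, path) -> None:
    """Write nodal fields on the mesh as an ASCII VTU (unstructured grid)."""
    path = Path(path)
    N, M = mesh.n_nodes, mesh.n_elements
    with path.open("w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(f'<Piece NumberOfPoints="{N}" NumberOfCells="{M}">\n')
        fh.write('<Points><DataArray type="Float64" NumberOfComponents="3" '
                 'format="ascii">\n')
        for x, y in mesh.points:
            fh.write(f"{x:.9g} {y:.9g} 0 ")
        fh.write('\n</DataArray></Points>\n<Cells>\n')
        fh.write('<DataArray type="Int32" Name="connectivity" format="ascii">\n')
        fh.write(" ".join(" ".join(map(str, tri)) for tri in mesh.tris))
        fh.write('\n</DataArray>\n<DataArray type="Int32" Name="offsets" '
                 'format="ascii">\n')
        fh.write(" ".join(str(3 * (i + 1)) for i in range(M)))
        fh.write('\n</DataArray>\n<DataArray type="UInt8" Name="types" '
                 'format="ascii">\n')
        fh.write(" ".join("5" for _ in range(M)))
        fh.write('\n</DataArray>\n</Cells>\n<PointData>\n')
        for name, arr in fields.items():
            fh.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
            fh.write(" ".join(f"{v:.9g}" for v in np.asarray(arr)))
            fh.write('\n</DataArray>\n')
        fh.write('</PointData>\n<CellData>\n')
        fh.write('<DataArray type="Int32" Name="subdomain" format="ascii">\n')
        fh.write(" ".join(map(str, mesh.labels)))
        fh.write('\n</DataArray>\n</CellData>\n</Piece>\n'
                 '</UnstructuredGrid>\n</VTKFile>\n')


def write_report_json(report, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def write_provenance(path, config=None, seed=None, **extra) -> None:
    """JSON sidecar carrying the config hash, seed and free-form metadata."""
    payload = dict(extra)
    if config is not None:
        payload["config_hash"] = config.hash
        payload["config"] = config.to_dict()
    if seed is not None:
        payload["seed"] = seed
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=1, default=float)
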