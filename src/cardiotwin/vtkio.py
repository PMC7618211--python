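"""Legacy-ASCII VTK unstructured-grid reader/writer for Mesh objects.

Point-data arrays written: fibre, sheet, normal (vectors), ab, tm, tv, pa, rt
(scalars), label (int codes per :data:`cardiotwin.geometry.LABELS`), plus any
extra per-node arrays supplied by the caller (e.g. activation times).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .geometry import Mesh

_CELL_TYPES = {4: 10, 8: 12}  # tetra, hexahedron
_CELL_SIZES = {10: 4, 12: 8}


def write_vtk(path, mesh: Mesh, extra_point_data=None):
    """Write a mesh (and optional extra per-node scalar arrays) to ``path``."""
    k = mesh.elements.shape[1]
    if k not in _CELL_TYPES:
        raise InvalidArgumentError(f"unsupported element arity {k}")
    extra = extra_point_data or {}
    n, e = mesh.n_nodes, mesh.elements.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncardiotwin mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for p in mesh.nodes:
            fh.write("%.17g %.17g %.17g\n" % tuple(p))
        fh.write(f"CELLS {e} {e * (k + 1)}\n")
        for el in mesh.elements:
            fh.write(str(k) + " " + " ".join(map(str, el)) + "\n")
        fh.write(f"CELL_TYPES {e}\n")
        fh.writelines(f"{_CELL_TYPES[k]}\n" for _ in range(e))
        scalars = {
            "ab": mesh.ab, "tm": mesh.tm, "tv": mesh.tv,
            "pa": mesh.pa, "rt": mesh.rt,
        }
        scalars.update(extra)
        fh.write(f"POINT_DATA {n}\n")
        fh.write(f"FIELD nodefields {len(scalars) + 4}\n")
        for name, vec in (
            ("fibre", mesh.fibres), ("sheet", mesh.sheets), ("normal", mesh.normals)
        ):
            fh.write(f"{name} 3 {n} double\n")
            for row in vec:
                fh.write("%.17g %.17g %.17g\n" % tuple(row))
        fh.write(f"label 1 {n} int\n")
        fh.write("\n".join(str(int(v)) for v in mesh.labels) + "\n")
        for name, arr in scalars.items():
            fh.write(f"{name} 1 {n} double\n")
            fh.write("\n".join("%.17g" % v for v in np.asarray(arr, float)) + "\n")


def write_vm_frames(path_prefix, mesh: Mesh, vm, times_ms):
    """Export selected membrane-potential frames (plus activation and
    repolarisation time maps) as VTK files for visualisation."""
    act = vm.activation_times()
    rep = vm.repolarisation_times()
    t = vm.times
    paths = []
    for tm in times_ms:
        k = int(np.argmin(np.abs(t - tm)))
        path = f"{path_prefix}_t{int(round(t[k]))}ms.vtk"
        write_vtk(
            path, mesh,
            extra_point_data={
                "vm": vm.data[:, k],
                "activation_time": act,
                "repolarisation_time": rep,
            },
        )
        paths.append(path)
    return paths


def read_vtk(path):
    """Read a mesh written by :func:`write_vtk`.

    Returns ``(mesh, extra)`` where ``extra`` holds any point-data arrays
    beyond the standard microstructure/coordinate fields.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))

    def find(word, start=0):
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise InvalidArgumentError(f"malformed VTK file: missing {word}")

    i = find("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = find("CELLS")
    e = int(tokens[i + 1])
    total = int(tokens[i + 2])
    raw = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
    k = int(raw[0])
    elements = raw.reshape(e, k + 1)[:, 1:]
    i = find("FIELD")
    narr = int(tokens[i + 2])
    pos = i + 3
    fields = {}
    for _ in range(narr):
        name = tokens[pos]
        ncomp = int(tokens[pos + 1])
        cnt = int(tokens[pos + 2])
        dtype = tokens[pos + 3]
        vals = np.array(
            tokens[pos + 4 : pos + 4 + ncomp * cnt],
            dtype=np.int64 if dtype == "int" else float,
        )
        fields[name] = vals.reshape(cnt, ncomp) if ncomp > 1 else vals
        pos += 4 + ncomp * cnt
    std = {"fibre", "sheet", "normal", "label", "ab", "tm", "tv", "pa", "rt"}
    mesh = Mesh(
        nodes=pts,
        elements=elements,
        fibres=fields["fibre"],
        sheets=fields["sheet"],
        normals=fields["normal"],
        ab=fields["ab"],
        tm=fields["tm"],
        tv=fields["tv"],
        pa=fields["pa"],
        rt=fields["rt"],
        labels=fields["label"].astype(np.int8),
    )
    extra = {k2: v for k2, v in fields.items() if k2 not in std}
    return mesh, extra
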