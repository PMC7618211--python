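"""Anisotropic graph Eikonal solver for ventricular activation.

Activation times are first-arrival shortest paths over the mesh edge graph,
with edge traversal times induced by the orthotropic conduction-velocity
tensor (fibre/sheet/normal speeds) in the bulk myocardium and isotropic fast
speeds on the endocardium (a dense apical region standing in for the
Purkinje-coupled endocardium, and a sparse region elsewhere). Graph geodesics
on coarse meshes overestimate continuous Eikonal distances slightly; the
inference stage calibrates speeds against this same solver, so the bias is
absorbed into the inferred speeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import InvalidArgumentError
from .geometry import Mesh

#: apex-to-base cutoff below which endocardium counts as the dense region
DENSE_AB_THRESHOLD = 0.4


@dataclass
class ConductionSpeeds:
    """Conduction speeds in cm/s."""

    Vf: float = 65.0   # myocardial, along fibre
    Vs: float = 48.0   # myocardial, along sheet
    Vn: float = 48.0   # myocardial, along sheet-normal
    Vd: float = 150.0  # endocardial dense (apical, Purkinje-coupled)
    Ve: float = 100.0  # endocardial sparse
    Vp: float = 300.0  # Purkinje surrogate (root-offset conversion only)

    def __post_init__(self):
        for name in ("Vf", "Vs", "Vn", "Vd", "Ve", "Vp"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    def myocardial_mm_per_ms(self):
        return np.array([self.Vf, self.Vs, self.Vn]) / 100.0


@dataclass
class RootNodes:
    """Earliest-activation sites with activation-time offsets."""

    indices: np.ndarray  # node ids
    offsets: np.ndarray  # ms

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.indices.size == 0:
            raise InvalidArgumentError("at least one root node required")
        if self.indices.size != self.offsets.size:
            raise InvalidArgumentError("indices and offsets must align")
        if np.any(self.offsets < 0):
            raise InvalidArgumentError("offsets must be non-negative")

    @property
    def n_root(self) -> int:
        return self.indices.size

    def to_json(self, path=None):
        payload = json.dumps(
            {"indices": self.indices.tolist(), "offsets": self.offsets.tolist()}
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, src):
        try:
            d = json.loads(src)
        except (json.JSONDecodeError, TypeError):
            with open(src) as fh:
                d = json.load(fh)
        return cls(np.asarray(d["indices"]), np.asarray(d["offsets"]))


@dataclass
class ActivationMap:
    """Per-node activation time in ms."""

    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame(
            {"node_id": np.arange(self.times.size), "t_a_ms": self.times}
        ).to_csv(path, index=False)


def edge_costs(mesh: Mesh, speeds: ConductionSpeeds, dense_ab=DENSE_AB_THRESHOLD):
    """Traversal time (ms) for every mesh edge.

    Myocardial edges use the orthotropic metric
    ``sqrt((p.f/Vf)^2 + (p.s/Vs)^2 + (p.n/Vn)^2)`` with the frame averaged
    between the edge endpoints; edges whose both endpoints are endocardial use
    the isotropic dense speed (both endpoints apical, ab < ``dense_ab``) or
    the sparse speed otherwise.
    """
    e = mesh.edges
    p = mesh.edge_vectors  # mm
    lengths = np.linalg.norm(p, axis=1)
    if np.any(lengths <= 0):
        raise InvalidArgumentError("zero-length edge")
    vmyo = speeds.myocardial_mm_per_ms()
    f, s, n = mesh.edge_frames()
    cost = np.sqrt(
        (np.sum(p * f, axis=1) / vmyo[0]) ** 2
        + (np.sum(p * s, axis=1) / vmyo[1]) ** 2
        + (np.sum(p * n, axis=1) / vmyo[2]) ** 2
    )
    endo = mesh.is_endocardial
    both_endo = endo[e[:, 0]] & endo[e[:, 1]]
    dense = both_endo & (mesh.ab[e[:, 0]] < dense_ab) & (mesh.ab[e[:, 1]] < dense_ab)
    sparse = both_endo & ~dense
    cost = np.where(dense, lengths / (speeds.Vd / 100.0), cost)
    cost = np.where(sparse, lengths / (speeds.Ve / 100.0), cost)
    return cost


def edge_cost(p, frame, speeds: ConductionSpeeds, regions=("myocardium", "myocardium")):
    """Traversal time (ms) of a single edge; see :func:`edge_costs`."""
    p = np.asarray(p, dtype=float)
    if np.linalg.norm(p) <= 0:
        raise InvalidArgumentError("zero-length edge")
    if regions[0] in ("dense", "sparse") and regions[1] in ("dense", "sparse"):
        v = speeds.Vd if regions == ("dense", "dense") else speeds.Ve
        return float(np.linalg.norm(p) / (v / 100.0))
    f, s, n = (np.asarray(v, dtype=float) for v in frame)
    vmyo = speeds.myocardial_mm_per_ms()
    return float(
        np.sqrt(
            (p @ f / vmyo[0]) ** 2 + (p @ s / vmyo[1]) ** 2 + (p @ n / vmyo[2]) ** 2
        )
    )


def solve_activation(
    mesh: Mesh,
    speeds: ConductionSpeeds,
    roots: RootNodes,
    dense_ab=DENSE_AB_THRESHOLD,
) -> ActivationMap:
    """Multi-source Dijkstra activation times with root offsets."""
    if np.any(roots.indices < 0) or np.any(roots.indices >= mesh.n_nodes):
        raise InvalidArgumentError("root node index out of range")
    costs = edge_costs(mesh, speeds, dense_ab)
    e = mesh.edges
    n = mesh.n_nodes
    # virtual source node n with directed arcs of weight t_i to the roots
    rows = np.concatenate([e[:, 0], e[:, 1], np.full(roots.n_root, n)])
    cols = np.concatenate([e[:, 1], e[:, 0], roots.indices])
    data = np.concatenate([costs, costs, roots.offsets])
    # duplicate (source, root) arcs: keep the minimum offset
    graph = coo_matrix((data, (rows, cols)), shape=(n + 1, n + 1)).tocsr()
    dup = np.bincount(roots.indices).max() if roots.n_root else 1
    if dup > 1:
        mins = {}
        for idx, off in zip(roots.indices, roots.offsets):
            mins[idx] = min(mins.get(idx, np.inf), off)
        for idx, off in mins.items():
            graph[n, idx] = off
    dist = dijkstra(graph, directed=True, indices=n)
    t = dist[:n]
    if np.any(np.isinf(t)):
        warnings.warn(
            f"{int(np.isinf(t).sum())} nodes unreachable from the root set; "
            "their activation time is infinite",
            stacklevel=2,
        )
    return ActivationMap(t)
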