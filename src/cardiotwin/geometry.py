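"""Idealized ventricular geometries with microstructure and coordinates.

Two fixture families stand in for image-derived anatomies: a rectangular slab
of regular hexahedra (for cable/tissue-scale comparisons against the
monodomain reference) and a truncated-ellipsoid biventricle built from an
implicit two-cavity solid (for whole-organ simulations and inference).

Meshes carry node-attached fibre/sheet/normal frames, the five normalised
ventricular coordinates (apex-to-base ``ab``, transmural ``tm``,
transventricular ``tv``, posterior-to-anterior ``pa``, rotational ``rt``) and
surface labels. The edge graph includes every vertex pair sharing an element
(for hexahedra this adds face/body diagonals), which keeps graph geodesics
close to Euclidean ones for the Eikonal solver and gives the smoothing
operator a well-connected 1-ring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay

from .errors import InvalidArgumentError

LABELS = {"interior": 0, "lv_endo": 1, "rv_endo": 2, "epi": 3, "base": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(eq=False)
class Mesh:
    """Unstructured ventricular mesh with per-node fields (positions in mm)."""

    nodes: np.ndarray              # (N, 3) mm
    elements: np.ndarray           # (E, 4) tets or (E, 8) hexes
    fibres: np.ndarray             # (N, 3) unit f
    sheets: np.ndarray             # (N, 3) unit s
    normals: np.ndarray            # (N, 3) unit n
    ab: np.ndarray                 # (N,) in [0, 1]
    tm: np.ndarray
    tv: np.ndarray
    pa: np.ndarray
    rt: np.ndarray
    labels: np.ndarray             # (N,) int codes per LABELS
    _edges: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Unique (i, j) node pairs (i < j) sharing an element."""
        if self._edges is None:
            pairs = []
            k = self.elements.shape[1]
            for a, b in combinations(range(k), 2):
                pairs.append(self.elements[:, [a, b]])
            e = np.vstack(pairs)
            e.sort(axis=1)
            self._edges = np.unique(e, axis=0)
        return self._edges

    @property
    def edge_vectors(self) -> np.ndarray:
        e = self.edges
        return self.nodes[e[:, 1]] - self.nodes[e[:, 0]]

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors, axis=1)

    def coord(self, name):
        return getattr(self, name)

    def edge_frames(self):
        """Orthonormal (f, s, n) per edge, endpoint-averaged then re-orthogonalised.

        Averaging the two endpoint frames breaks mutual orthogonality, which
        would make the anisotropic metric decomposition inexact; a
        Gram-Schmidt pass restores it. Cached on the mesh.
        """
        cached = self.op_cache.get("edge-frames")
        if cached is not None:
            return cached
        e = self.edges
        f = 0.5 * (self.fibres[e[:, 0]] + self.fibres[e[:, 1]])
        s = 0.5 * (self.sheets[e[:, 0]] + self.sheets[e[:, 1]])
        f /= np.maximum(np.linalg.norm(f, axis=1, keepdims=True), 1e-12)
        s -= np.sum(s * f, axis=1, keepdims=True) * f
        s /= np.maximum(np.linalg.norm(s, axis=1, keepdims=True), 1e-12)
        n = np.cross(f, s)
        self.op_cache["edge-frames"] = (f, s, n)
        return f, s, n

    @property
    def op_cache(self) -> dict:
        """Scratch cache for derived operators (smoothing matrix, ECG weights)."""
        if not hasattr(self, "_op_cache"):
            self._op_cache = {}
        return self._op_cache

    @property
    def is_endocardial(self) -> np.ndarray:
        return (self.labels == LABELS["lv_endo"]) | (self.labels == LABELS["rv_endo"])

    def validate(self, tol=1e-6):
        """Check frame orthonormality, coordinate bounds and edge positivity."""
        for u, v in (
            (self.fibres, self.sheets),
            (self.sheets, self.normals),
            (self.fibres, self.normals),
        ):
            if np.max(np.abs(np.sum(u * v, axis=1))) > tol:
                raise AssertionError("fibre frame not orthogonal")
        for v in (self.fibres, self.sheets, self.normals):
            if np.max(np.abs(np.linalg.norm(v, axis=1) - 1)) > tol:
                raise AssertionError("fibre frame not unit length")
        for c in (self.ab, self.tm, self.tv, self.pa, self.rt):
            if c.min() < -tol or c.max() > 1 + tol:
                raise AssertionError("coordinate outside [0, 1]")
        if np.any(self.edge_lengths <= 0):
            raise AssertionError("zero-length edge")
        return True


# ---------------------------------------------------------------------------
# Slab
# ---------------------------------------------------------------------------


def generate_slab(nx, ny, nz, spacing, fibre_angle=0.0) -> Mesh:
    """Regular hexahedral slab; fibres rotated by ``fibre_angle`` about z.

    Coordinates are the normalised axis positions: ``ab`` along x, ``tv`` and
    ``pa`` along y, ``tm`` along z (z=0 face is labelled lv_endo, z=max epi);
    ``rt`` mirrors ``ab``.
    """
    if nx < 2 or ny < 2 or nz < 2 or spacing <= 0:
        raise InvalidArgumentError("need nx, ny, nz >= 2 and spacing > 0")
    xs = np.arange(nx) * spacing
    ys = np.arange(ny) * spacing
    zs = np.arange(nz) * spacing
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return ix + nx * (iy + ny * iz)

    elems = []
    for iz in range(nz - 1):
        for iy in range(ny - 1):
            for ix in range(nx - 1):
                elems.append(
                    [
                        nid(ix, iy, iz), nid(ix + 1, iy, iz),
                        nid(ix + 1, iy + 1, iz), nid(ix, iy + 1, iz),
                        nid(ix, iy, iz + 1), nid(ix + 1, iy, iz + 1),
                        nid(ix + 1, iy + 1, iz + 1), nid(ix, iy + 1, iz + 1),
                    ]
                )
    elements = np.array(elems, dtype=np.int64)
    n = nodes.shape[0]
    th = np.deg2rad(fibre_angle)
    f = np.tile([np.cos(th), np.sin(th), 0.0], (n, 1))
    s = np.tile([-np.sin(th), np.cos(th), 0.0], (n, 1))
    nn = np.tile([0.0, 0.0, 1.0], (n, 1))
    ab = nodes[:, 0] / xs[-1]
    tv = nodes[:, 1] / ys[-1]
    pa = nodes[:, 1] / ys[-1]
    tm = nodes[:, 2] / zs[-1]
    rt = ab.copy()
    labels = np.full(n, LABELS["interior"], dtype=np.int8)
    labels[np.isclose(nodes[:, 2], 0.0)] = LABELS["lv_endo"]
    labels[np.isclose(nodes[:, 2], zs[-1])] = LABELS["epi"]
    return Mesh(nodes, elements, f, s, nn, ab, tm, tv, pa, rt, labels)


# ---------------------------------------------------------------------------
# Idealized biventricle
# ---------------------------------------------------------------------------

# implicit-solid constants (mm): outer (epicardial) ellipsoid and two cavities
_EPI_C, _EPI_R = np.array([0.0, 0.0, -5.0]), np.array([35.0, 30.0, 42.0])
_LV_C, _LV_R = np.array([-11.0, 0.0, -3.0]), np.array([13.0, 14.0, 30.0])
_RV_C, _RV_R = np.array([13.0, 0.0, -1.0]), np.array([16.0, 17.0, 29.0])
_Z_BASE = 15.0
_HELIX_ENDO, _HELIX_EPI = 60.0, -60.0  # degrees


def _quad(x, c, r):
    """Ellipsoid quadratic: < 1 inside, 1 on the surface."""
    return np.sum(((x - c) / r) ** 2, axis=-1)


def _inside_myocardium(x):
    return (
        (_quad(x, _EPI_C, _EPI_R) <= 1.0)
        & (_quad(x, _LV_C, _LV_R) >= 1.0)
        & (_quad(x, _RV_C, _RV_R) >= 1.0)
        & (x[..., 2] <= _Z_BASE)
    )


def _tm_field(x):
    """Analytic transmural coordinate: 0 on either endocardium, 1 on epi."""
    d_endo = np.minimum(_quad(x, _LV_C, _LV_R), _quad(x, _RV_C, _RV_R)) - 1.0
    d_epi = 1.0 - _quad(x, _EPI_C, _EPI_R)
    d_endo = np.maximum(d_endo, 0.0)
    d_epi = np.maximum(d_epi, 0.0)
    den = d_endo + d_epi
    return np.where(den > 0, d_endo / np.maximum(den, 1e-30), 0.5)


def generate_idealized_biventricle(
    n_circumferential=26, n_longitudinal=18, n_transmural=3
) -> Mesh:
    """Truncated-ellipsoid two-cavity geometry with analytic coordinates.

    Nodes are lattice samples of an implicit biventricular solid (outer
    epicardial ellipsoid minus LV/RV cavity ellipsoids, truncated at the base
    plane), with surface nodes snapped onto their analytic surface, connected
    by Delaunay tetrahedra. The fibre helix angle varies linearly from +60 deg
    on the endocardium to -60 deg on the epicardium.
    """
    if n_circumferential < 3 or n_longitudinal < 3 or n_transmural < 3:
        raise InvalidArgumentError("all counts must be >= 3")
    ext_xy = 2 * max(_EPI_R[0], _EPI_R[1])
    ext_z = _Z_BASE - (_EPI_C[2] - _EPI_R[2])
    wall = float(_EPI_R[0] + _EPI_C[0] - (_RV_C[0] + _RV_R[0]))  # RV free wall
    h_xy = min(ext_xy / n_circumferential, 4.0 * wall / n_transmural)
    h_z = ext_z / n_longitudinal
    xs = np.arange(-_EPI_R[0] + _EPI_C[0], _EPI_R[0] + _EPI_C[0] + h_xy, h_xy)
    ys = np.arange(-_EPI_R[1] + _EPI_C[1], _EPI_R[1] + _EPI_C[1] + h_xy, h_xy)
    zs = np.arange(_EPI_C[2] - _EPI_R[2], _Z_BASE + h_z / 2, h_z)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = _inside_myocardium(pts)
    pts = pts[keep]

    # classify boundary lattice nodes by which constraint their 6-neighbourhood
    # violates, then snap them onto the corresponding analytic surface
    step = np.array([[h_xy, 0, 0], [-h_xy, 0, 0], [0, h_xy, 0],
                     [0, -h_xy, 0], [0, 0, h_z], [0, 0, -h_z]])
    labels = np.full(pts.shape[0], LABELS["interior"], dtype=np.int8)
    for i in range(pts.shape[0]):
        nb = pts[i] + step
        out = ~_inside_myocardium(nb)
        if not out.any():
            continue
        nb_out = nb[out]
        if np.any(_quad(nb_out, _LV_C, _LV_R) < 1.0):
            labels[i] = LABELS["lv_endo"]
        elif np.any(_quad(nb_out, _RV_C, _RV_R) < 1.0):
            labels[i] = LABELS["rv_endo"]
        elif np.any(nb_out[:, 2] > _Z_BASE):
            labels[i] = LABELS["base"]
        else:
            labels[i] = LABELS["epi"]

    def snap(mask, c, r):
        q = _quad(pts[mask], c, r)
        pts[mask] = c + (pts[mask] - c) / np.sqrt(q)[:, None]

    snap(labels == LABELS["lv_endo"], _LV_C, _LV_R)
    snap(labels == LABELS["rv_endo"], _RV_C, _RV_R)
    snap(labels == LABELS["epi"], _EPI_C, _EPI_R)
    pts[labels == LABELS["base"], 2] = _Z_BASE
    # snapping can push epi nodes past the base plane
    pts[:, 2] = np.minimum(pts[:, 2], _Z_BASE)

    # deterministic jitter of interior nodes avoids degenerate Delaunay ties
    rng = np.random.default_rng(20_240_101)
    jit = (rng.random(pts.shape) - 0.5) * (1e-3 * h_xy)
    jit[labels != LABELS["interior"]] = 0.0
    pts = pts + jit

    tri = Delaunay(pts)
    tets = tri.simplices
    cent = pts[tets].mean(axis=1)
    a, b, c, d = (pts[tets[:, k]] for k in range(4))
    vol = np.abs(np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)) / 6.0
    good = _inside_myocardium(cent) & (vol > 1e-6 * h_xy**3)
    # drop oversized sliver tets bridging concave regions (cavity mouths)
    edge_max = np.zeros(tets.shape[0])
    for i, j in combinations(range(4), 2):
        edge_max = np.maximum(
            edge_max, np.linalg.norm(pts[tets[:, i]] - pts[tets[:, j]], axis=1)
        )
    good &= edge_max <= 2.2 * max(h_xy, h_z)
    tets = tets[good]

    used = np.unique(tets)
    remap = -np.ones(pts.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = pts[used]
    labels = labels[used]
    elements = remap[tets]

    # keep the largest connected component of the element graph
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pairs = np.vstack([elements[:, [i, j]] for i, j in combinations(range(4), 2)])
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
        shape=(nodes.shape[0],) * 2,
    )
    ncomp, comp = connected_components(adj, directed=False)
    if ncomp > 1:
        main = np.argmax(np.bincount(comp))
        keep_n = comp == main
        remap2 = -np.ones(nodes.shape[0], dtype=np.int64)
        remap2[keep_n] = np.arange(keep_n.sum())
        elements = remap2[elements[np.all(keep_n[elements], axis=1)]]
        nodes = nodes[keep_n]
        labels = labels[keep_n]

    # analytic coordinates
    tm = np.clip(_tm_field(nodes), 0.0, 1.0)
    z = nodes[:, 2]
    ab = (z - z.min()) / (_Z_BASE - z.min())
    ab = np.clip(ab, 0.0, 1.0)
    x, y = nodes[:, 0], nodes[:, 1]
    tv = (x - x.min()) / (x.max() - x.min())
    pa = (y - y.min()) / (y.max() - y.min())
    theta = np.arctan2(y - _EPI_C[1], x - _EPI_C[0])  # 0 at +x (RV side)
    rt = ((theta + np.pi / 2) / (2 * np.pi)) % 1.0  # seam on the posterior side

    f, s, n = _rule_based_fibres(nodes, tm)
    mesh = Mesh(nodes, elements.astype(np.int64), f, s, n, ab, tm, tv, pa, rt, labels)
    mesh.validate()
    return mesh


def helix_angle(tm):
    """Linear endo->epi fibre helix rule, degrees."""
    return _HELIX_ENDO + (_HELIX_EPI - _HELIX_ENDO) * np.asarray(tm)


def _rule_based_fibres(nodes, tm):
    """Orthonormal (f, s, n) from the linear helix rule on the tm gradient."""
    eps = 0.1
    grad = np.empty_like(nodes)
    for k in range(3):
        dp = nodes.copy()
        dm = nodes.copy()
        dp[:, k] += eps
        dm[:, k] -= eps
        grad[:, k] = (_tm_field(dp) - _tm_field(dm)) / (2 * eps)
    gnorm = np.linalg.norm(grad, axis=1, keepdims=True)
    r = grad / np.maximum(gnorm, 1e-12)
    # tm plateaus (septal mid-wall ridge, sub-apical region): fall back to the
    # geometric radial direction from the epicardial centre
    flat = gnorm.ravel() < 1e-4
    if flat.any():
        alt = nodes[flat] - _EPI_C
        alt_n = np.linalg.norm(alt, axis=1, keepdims=True)
        alt = np.where(alt_n > 1e-9, alt / np.maximum(alt_n, 1e-9), [1.0, 0.0, 0.0])
        r[flat] = alt
    zax = np.array([0.0, 0.0, 1.0])
    c = np.cross(np.tile(zax, (nodes.shape[0], 1)), r)
    cn = np.linalg.norm(c, axis=1)
    bad = cn < 1e-6  # radial parallel to z (apex): fall back to x axis seed
    c[bad] = np.cross(np.array([1.0, 0.0, 0.0]), r[bad])
    c /= np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
    l = np.cross(r, c)
    al = np.deg2rad(helix_angle(tm))[:, None]
    f = np.cos(al) * c + np.sin(al) * l
    s = r - np.sum(r * f, axis=1, keepdims=True) * f
    s /= np.maximum(np.linalg.norm(s, axis=1, keepdims=True), 1e-12)
    n = np.cross(f, s)
    return f, s, n


# ---------------------------------------------------------------------------
# Electrodes
# ---------------------------------------------------------------------------

#: fractional torso-ellipsoid placement rules: (azimuth deg from anterior
#: towards the right, fractional height in [-1, 1])
_ELECTRODE_RULES = {
    "RA": (110.0, 0.85),
    "LA": (-110.0, 0.85),
    "LL": (-60.0, -0.95),
    "V1": (40.0, -0.10),
    "V2": (20.0, -0.10),
    "V3": (0.0, -0.20),
    "V4": (-20.0, -0.25),
    "V5": (-45.0, -0.25),
    "V6": (-70.0, -0.25),
}

LEAD_NAMES = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class ElectrodeSet:
    """Nine measurement points plus the 8-independent-lead map."""

    positions: dict  # name -> (3,) mm

    @property
    def names(self):
        return tuple(self.positions)

    def lead_map(self):
        """name -> {electrode: coefficient} for the 8 independent leads."""
        wct = {"RA": 1 / 3, "LA": 1 / 3, "LL": 1 / 3}
        leads = {
            "I": {"LA": 1.0, "RA": -1.0},
            "II": {"LL": 1.0, "RA": -1.0},
        }
        for v in ("V1", "V2", "V3", "V4", "V5", "V6"):
            leads[v] = {v: 1.0, **{k: -w for k, w in wct.items()}}
        return leads

    def to_json(self, path=None):
        payload = json.dumps(
            {k: list(map(float, v)) for k, v in self.positions.items()}, indent=1
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
        return cls({k: np.asarray(v, dtype=float) for k, v in d.items()})


def _orientation_axis(mesh, coord):
    """Unit x-y-plane direction of increasing ``coord`` over the mesh."""
    c = mesh.coord(coord)
    hi = mesh.nodes[c >= np.quantile(c, 0.8)].mean(axis=0)
    lo = mesh.nodes[c <= np.quantile(c, 0.2)].mean(axis=0)
    d = hi - lo
    d[2] = 0.0
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        raise InvalidArgumentError(f"mesh {coord} field has no in-plane direction")
    return d / nrm


def place_electrodes(mesh: Mesh, torso_scale=3.0) -> ElectrodeSet:
    """Place the 9 standard electrodes on a torso-scale bounding ellipsoid.

    The ellipsoid is the mesh bounding box scaled by ``torso_scale``; azimuth
    angles are measured from the mesh's anterior direction (increasing ``pa``)
    towards its right side (increasing ``tv``), so mirrored meshes produce
    mirrored electrode positions.
    """
    if torso_scale <= 1:
        raise InvalidArgumentError("torso_scale must exceed 1")
    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    centre = 0.5 * (lo + hi)
    semi = 0.5 * (hi - lo) * torso_scale
    semi = np.maximum(semi, 1e-6)
    right = _orientation_axis(mesh, "tv")
    ant = _orientation_axis(mesh, "pa")
    # orthogonalise anterior against right in the x-y plane
    ant = ant - np.dot(ant, right) * right
    if np.linalg.norm(ant) < 1e-9:
        ant = np.array([-right[1], right[0], 0.0])
    ant /= np.linalg.norm(ant)
    positions = {}
    for name, (az, hfrac) in _ELECTRODE_RULES.items():
        a = np.deg2rad(az)
        d = np.cos(a) * ant + np.sin(a) * right
        positions[name] = centre + np.array(
            [semi[0] * d[0], semi[1] * d[1], semi[2] * hfrac]
        )
    return ElectrodeSet(positions)
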