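"""Pseudo-diffusion reaction-Eikonal forward model.

The reaction operator is solved once per node by shifting a precomputed
action potential (from the APD lookup table) to the node's Eikonal activation
time; the diffusion operator is approximated during repolarisation by
repeated application of an orthotropic neighbour-averaging smoothing
operator. The APD field itself is a min-max-normalised weighted linear sum of
the four ventricular coordinates, mapped onto a physiological
[APD_min, APD_max] range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.sparse import coo_matrix, eye, diags

from .cells import APLookupTable, WAVEFORM_SAMPLES
from .eikonal import ActivationMap, ConductionSpeeds
from .errors import InvalidArgumentError
from .geometry import Mesh


@dataclass
class APDFieldParams:
    """Linear APD-gradient field parameters."""

    g_ab: float = 0.0
    g_tm: float = 0.0
    g_pa: float = 0.0
    g_tv: float = 0.0
    apd_min: float = 200.0  # ms
    apd_max: float = 300.0  # ms

    def __post_init__(self):
        if not self.apd_min < self.apd_max:
            raise InvalidArgumentError("apd_min must be < apd_max")

    def as_dict(self):
        return {
            "g_ab": self.g_ab, "g_tm": self.g_tm, "g_pa": self.g_pa,
            "g_tv": self.g_tv, "apd_min": self.apd_min, "apd_max": self.apd_max,
        }


@dataclass
class SmoothingConfig:
    """Schedule and strength of the pseudo-diffusion smoothing operator."""

    k_i: float = 10.0            # mm^-1 self-weight (1/self-distance)
    dt_B: float = 20.0           # ms between smoothing applications
    window: tuple = (100.0, 450.0)  # ms, approx. end of activation -> end of repol
    dt_A: float = 1.0            # ms reaction output sampling step

    def __post_init__(self):
        if self.k_i <= 0:
            raise InvalidArgumentError("k_i must be positive")
        if not (self.dt_B >= self.dt_A > 0):
            raise InvalidArgumentError("need dt_B >= dt_A > 0")
        if self.window is not None and not self.window[0] < self.window[1]:
            raise InvalidArgumentError("window start must precede end")


@dataclass
class VmSolution:
    """Node x time membrane potential at a fixed sampling rate."""

    data: np.ndarray      # (N, T+1) mV
    rate: float = 1000.0  # Hz
    duration: float = 0.0  # ms

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        expected = int(round(self.duration * self.rate / 1000.0)) + 1
        if self.data.shape[1] != expected:
            raise InvalidArgumentError(
                f"sample count {self.data.shape[1]} != duration*rate+1 ({expected})"
            )

    @property
    def n_nodes(self):
        return self.data.shape[0]

    @property
    def times(self):
        return np.arange(self.data.shape[1]) * (1000.0 / self.rate)

    def repolarisation_times(self, frac=0.9):
        """Per-node last crossing of ``frac`` recovery towards rest (ms)."""
        rest = self.data[:, 0]
        peak = self.data.max(axis=1)
        level = rest + (1 - frac) * (peak - rest)
        above = self.data >= level[:, None]
        idx = self.data.shape[1] - 1 - np.argmax(above[:, ::-1], axis=1)
        return idx * (1000.0 / self.rate)

    def activation_times(self):
        """Per-node steepest-upstroke time (ms)."""
        return np.argmax(np.diff(self.data, axis=1), axis=1) * (1000.0 / self.rate)

    def save(self, path):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("vm", data=self.data, compression="gzip")
            fh.attrs["rate"] = self.rate
            fh.attrs["duration"] = self.duration

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as fh:
            return cls(fh["vm"][:], float(fh.attrs["rate"]), float(fh.attrs["duration"]))


def apd_field(mesh: Mesh, params: APDFieldParams):
    """Integer-ms APD per node from the linear coordinate-gradient model."""
    q = (
        params.g_ab * mesh.ab
        + params.g_tm * mesh.tm
        + params.g_pa * mesh.pa
        + params.g_tv * mesh.tv
    )
    span = q.max() - q.min()
    if span <= 1e-12:
        warnings.warn(
            "degenerate APD field (all gradient weights zero or constant "
            "coordinates); using uniform mid-range APD",
            stacklevel=2,
        )
        mid = 0.5 * (params.apd_min + params.apd_max)
        return np.full(mesh.n_nodes, int(round(mid)), dtype=np.int64)
    qn = (q - q.min()) / span
    apd = qn * (params.apd_max - params.apd_min) + params.apd_min
    return np.rint(apd).astype(np.int64)


def assemble_vm(
    mesh: Mesh,
    activation: ActivationMap,
    apd,
    table: APLookupTable,
    duration: float,
    dt_A: float = 1.0,
    check_coverage: bool = True,
) -> VmSolution:
    """Reaction-operator solution: shifted lookup APs on the activation map.

    ``U(x, t) = U_rest`` before activation and the (linearly interpolated)
    table waveform of the node's APD afterwards. ``check_coverage=False``
    permits deliberately truncated windows (e.g. QRS-only assembly).
    """
    apd = np.asarray(apd)
    t_a = activation.times
    finite = t_a[np.isfinite(t_a)]
    if finite.size == 0:
        raise InvalidArgumentError("no node has a finite activation time")
    if check_coverage and duration < finite.max() + table.apd_min:
        raise InvalidArgumentError("duration does not cover activation plus APD")
    rows = table.key_index(apd)  # raises KeyError naming offending values
    n_t = int(round(duration / dt_A)) + 1
    t = np.arange(n_t) * dt_A
    tau = t[None, :] - t_a[:, None]  # time since local activation
    idx = np.floor(tau).astype(np.int64)
    frac = tau - idx
    np.clip(idx, 0, WAVEFORM_SAMPLES - 2, out=idx)
    wf = table.waveforms[rows]
    u0 = np.take_along_axis(wf, idx, axis=1)
    u1 = np.take_along_axis(wf, idx + 1, axis=1)
    u = u0 * (1.0 - frac) + u1 * frac
    u[tau < 0] = table.u_rest
    u[tau >= WAVEFORM_SAMPLES - 1] = wf[:, -1][
        np.nonzero(tau >= WAVEFORM_SAMPLES - 1)[0]
    ]
    rate = 1000.0 / dt_A
    return VmSolution(u, rate=rate, duration=duration)


def adjacency_weights(mesh: Mesh, speeds: ConductionSpeeds):
    """Per-edge orthotropic adjacency weight k_m (mm^-1).

    The edge most aligned with the fastest conduction direction gets the
    largest weight; k_m is bounded between min(V)/max(V) / |p| and 1 / |p|.
    """
    e = mesh.edges
    p = mesh.edge_vectors
    if np.any(np.linalg.norm(p, axis=1) <= 0):
        raise InvalidArgumentError("zero-length edge")
    v = np.array([speeds.Vf, speeds.Vs, speeds.Vn])
    vmax = v.max()
    f, s, n = mesh.edge_frames()
    return 1.0 / np.sqrt(
        (vmax / v[0] * np.sum(p * f, axis=1)) ** 2
        + (vmax / v[1] * np.sum(p * s, axis=1)) ** 2
        + (vmax / v[2] * np.sum(p * n, axis=1)) ** 2
    )


def smoothing_matrix(mesh: Mesh, speeds: ConductionSpeeds, k_i: float):
    """Sparse operator S applying one synchronous smoothing pass (cached)."""
    key = ("smoothing", speeds.Vf, speeds.Vs, speeds.Vn, k_i)
    cached = mesh.op_cache.get(key)
    if cached is not None:
        return cached
    k_m = adjacency_weights(mesh, speeds)
    e = mesh.edges
    n = mesh.n_nodes
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.concatenate([k_m, k_m])
    A = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    denom = np.asarray(A.sum(axis=1)).ravel() + k_i
    S = (diags(1.0 / denom) @ (A + k_i * eye(n, format="csr"))).tocsr()
    mesh.op_cache[key] = S
    return S


def smooth(frame, weights_matrix):
    """One synchronous application of the smoothing operator to a frame."""
    return weights_matrix @ np.asarray(frame, dtype=float)


def run_pseudo_diffusion_re(
    mesh: Mesh,
    activation: ActivationMap,
    apd_params: APDFieldParams,
    table: APLookupTable,
    speeds: ConductionSpeeds,
    smoothing: SmoothingConfig | None = None,
    duration: float = 500.0,
) -> VmSolution:
    """Full forward model: assemble the reaction solution, then smooth.

    Within the smoothing window each output frame at time t receives
    ``n_B = floor((t - start) / dt_B) + 1`` cumulative applications of the
    smoothing operator; frames outside the window pass through unchanged.
    """
    smoothing = smoothing if smoothing is not None else SmoothingConfig()
    apd = apd_field(mesh, apd_params)
    vm = assemble_vm(mesh, activation, apd, table, duration, smoothing.dt_A)
    if smoothing.window is None:
        return vm
    start, end = smoothing.window
    t = vm.times
    n_b = np.zeros(t.size, dtype=np.int64)
    in_win = (t >= start) & (t <= end)
    n_b[in_win] = np.floor((t[in_win] - start) / smoothing.dt_B).astype(np.int64) + 1
    if n_b.max() == 0:
        return vm
    S = smoothing_matrix(mesh, speeds, smoothing.k_i)
    data = np.asfortranarray(vm.data)
    # n_B is non-decreasing across the window, so the frames needing at least
    # k applications form one contiguous column range per level k
    win = np.nonzero(in_win)[0]
    nb_win = n_b[win]
    for level in range(1, int(nb_win.max()) + 1):
        i0 = win[int(np.searchsorted(nb_win, level))]
        i1 = win[-1]
        data[:, i0 : i1 + 1] = S @ data[:, i0 : i1 + 1]
    return VmSolution(data, rate=vm.rate, duration=vm.duration)
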