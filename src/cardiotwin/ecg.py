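"""Pseudo-ECG forward computation, normalisation, biomarkers and discrepancy.

The pseudo-ECG treats the torso as an infinite homogeneous volume conductor:
the potential at an electrode is the volume integral of the transmembrane
potential gradient against the gradient of 1/r to the electrode. Because the
absolute scale is arbitrary, simulated recordings are rescaled by a single
cross-lead factor to the R-wave amplitude of a reference recording,
preserving the inter-lead R-progression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateSignalError,
    InvalidArgumentError,
    SingularKernelError,
)
from .geometry import LEAD_NAMES, ElectrodeSet, Mesh
from .re_model import VmSolution


@dataclass
class ECGRecording:
    """Eight independent leads (I, II, V1-V6) at a fixed sampling rate."""

    data: np.ndarray              # (8, T) normalised amplitude
    rate: float = 1000.0          # Hz
    rr: float = 1.0               # s
    lead_names: tuple = LEAD_NAMES

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        if self.data.shape[0] != len(self.lead_names):
            raise InvalidArgumentError("one row per lead required")

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def times(self):
        return np.arange(self.n_samples) * (1000.0 / self.rate)

    def lead(self, name):
        return self.data[self.lead_names.index(name)]

    def to_csv(self, path, sidecar=True):
        import pandas as pd

        df = pd.DataFrame({"time_ms": self.times})
        for i, name in enumerate(self.lead_names):
            df[name] = self.data[i]
        df.to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump({"rate_hz": self.rate, "rr_s": self.rr}, fh)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c != "time_ms")
        rate, rr = 1000.0, 1.0
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
            rate, rr = meta.get("rate_hz", rate), meta.get("rr_s", rr)
        except FileNotFoundError:
            if len(df) > 1:
                rate = 1000.0 / (df["time_ms"].iloc[1] - df["time_ms"].iloc[0])
        return cls(df[list(names)].to_numpy().T, rate=rate, rr=rr, lead_names=names)


@dataclass
class Biomarkers:
    """Lead-averaged repolarisation biomarkers (times in ms)."""

    qt: float
    qtc: float
    tpe: float
    t_amplitude: float
    t_polarity: np.ndarray       # sign per lead
    qrs_duration: float
    tpeak_dispersion_v3_v5: float

    def as_dict(self):
        return {
            "qt_ms": self.qt, "qtc_ms": self.qtc, "tpe_ms": self.tpe,
            "t_amplitude": self.t_amplitude,
            "qrs_duration_ms": self.qrs_duration,
            "tpeak_dispersion_v3_v5_ms": self.tpeak_dispersion_v3_v5,
        }


@dataclass
class DiscrepancyConfig:
    """Weights of the PCC and amplitude terms of the inference discrepancy."""

    w_p: float = 100.0
    w_r: float = 2.0

    def __post_init__(self):
        if self.w_p < 0 or self.w_r < 0 or (self.w_p == 0 and self.w_r == 0):
            raise InvalidArgumentError("weights must be >= 0 and not both zero")


# ---------------------------------------------------------------------------
# Pseudo-ECG
# ---------------------------------------------------------------------------


def _element_gradients(mesh: Mesh):
    """Per-element linear gradient operators and volumes.

    Returns ``(G, vol)`` with ``G`` of shape (E, 3, k) mapping element nodal
    values to the constant element gradient (tetrahedra: linear FEM;
    hexahedra: axis-aligned face-mean differences).
    """
    el = mesh.elements
    x = mesh.nodes[el]  # (E, k, 3)
    if el.shape[1] == 4:
        m = np.stack([x[:, i] - x[:, 0] for i in (1, 2, 3)], axis=1)  # (E,3,3)
        det = np.linalg.det(m)
        if np.any(np.abs(det) < 1e-15):
            raise InvalidArgumentError("degenerate tetrahedron")
        minv = np.linalg.inv(m)  # rows of m are edge vectors
        g = np.empty((el.shape[0], 3, 4))
        g[:, :, 1:] = minv
        g[:, :, 0] = -minv.sum(axis=2)
        vol = np.abs(det) / 6.0
        return g, vol
    if el.shape[1] == 8:
        faces = {
            0: ([1, 2, 5, 6], [0, 3, 4, 7]),  # x
            1: ([2, 3, 6, 7], [0, 1, 4, 5]),  # y
            2: ([4, 5, 6, 7], [0, 1, 2, 3]),  # z
        }
        h = np.empty((el.shape[0], 3))
        g = np.zeros((el.shape[0], 3, 8))
        for ax, (plus, minus) in faces.items():
            h[:, ax] = x[:, plus, ax].mean(axis=1) - x[:, minus, ax].mean(axis=1)
            for p in plus:
                g[:, ax, p] = 0.25 / h[:, ax]
            for p in minus:
                g[:, ax, p] = -0.25 / h[:, ax]
        vol = np.abs(np.prod(h, axis=1))
        return g, vol
    raise InvalidArgumentError("elements must be tetrahedra or hexahedra")


def electrode_weights(mesh: Mesh, electrodes: ElectrodeSet):
    """Per-electrode node-weight vectors w such that phi(t) = w . U(t).

    Cached on the mesh per electrode layout.
    """
    key = ("ecg-weights",) + tuple(
        (name, *np.round(pos, 9)) for name, pos in electrodes.positions.items()
    )
    cached = mesh.op_cache.get(key)
    if cached is not None:
        return cached
    g, vol = _element_gradients(mesh)
    el = mesh.elements
    cent = mesh.nodes[el].mean(axis=1)  # (E, 3)
    size = np.max(
        np.linalg.norm(mesh.nodes[el] - cent[:, None, :], axis=2), axis=1
    )
    weights = {}
    for name, pos in electrodes.positions.items():
        r = pos[None, :] - cent  # (E, 3)
        dist = np.linalg.norm(r, axis=1)
        if np.any(dist <= size):
            raise SingularKernelError(
                f"electrode {name} lies inside or on a mesh element"
            )
        grad_inv_r = r / dist[:, None] ** 3  # grad_x(1/|e - x|) at the element
        # phi = -sum_el vol * gradU . grad(1/r); gradU = G @ u_el
        contrib = -vol[:, None] * np.einsum("ej,eji->ei", grad_inv_r, g)
        w = np.zeros(mesh.n_nodes)
        np.add.at(w, el.ravel(), contrib.ravel())
        weights[name] = w
    mesh.op_cache[key] = weights
    return weights


def pseudo_ecg(
    vm: VmSolution, mesh: Mesh, electrodes: ElectrodeSet, rr: float = 1.0
) -> ECGRecording:
    """Unnormalised 8-lead pseudo-ECG of a membrane-potential solution."""
    w = electrode_weights(mesh, electrodes)
    phi = {name: wv @ vm.data for name, wv in w.items()}  # (T,) each
    lead_map = electrodes.lead_map()
    data = np.stack(
        [
            sum(coef * phi[elec] for elec, coef in lead_map[lead].items())
            for lead in LEAD_NAMES
        ]
    )
    return ECGRecording(data, rate=vm.rate, rr=rr)


def normalise_r_progression(
    sim: ECGRecording, reference: ECGRecording, qrs_window=(0.0, 120.0)
) -> ECGRecording:
    """Scale all simulated leads by one factor matching the reference R wave.

    The factor is max|R_reference| / max|R_sim| over all leads within the QRS
    window, so relative lead amplitudes (the R-progression) are preserved.
    """
    if sim.lead_names != reference.lead_names:
        raise InvalidArgumentError("lead sets differ")

    def qrs_amp(ecg):
        t = ecg.times
        m = (t >= qrs_window[0]) & (t <= qrs_window[1])
        return np.abs(ecg.data[:, m]).max() if m.any() else np.abs(ecg.data).max()

    a_sim = qrs_amp(sim)
    if a_sim <= 0:
        raise DegenerateSignalError("simulated QRS amplitude is zero")
    scale = qrs_amp(reference) / a_sim
    return ECGRecording(sim.data * scale, rate=sim.rate, rr=sim.rr,
                        lead_names=sim.lead_names)


def qtc_fridericia(qt, rr):
    """Fridericia-corrected QT: QT / RR^(1/3) with QT in ms and RR in s."""
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise InvalidArgumentError("RR must be positive")
    out = np.asarray(qt, dtype=float) / rr ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def _t_end_tangent(t, x, i_peak, polarity, limb_frac=0.3):
    """Maximum-slope tangent intersection with the isoelectric baseline.

    The tangent is anchored on the final descending limb of the T complex
    (after the last excursion above ``limb_frac`` of the peak amplitude), so
    multi-lobed T waves are measured to the end of their last lobe rather
    than truncated at the first.
    """
    seg = x[i_peak:]
    if seg.size < 3:
        return t[-1]
    ts = t[i_peak:]
    amp = abs(x[i_peak])
    above = np.nonzero(polarity * seg >= limb_frac * amp)[0]
    i_last = int(above[-1]) if above.size else 0
    slope = np.gradient(seg, ts)
    j0 = max(0, i_last - 40)
    j1 = min(seg.size, i_last + 5)
    i_m = j0 + int(np.argmin(polarity * slope[j0:j1]))
    m = slope[i_m]
    if polarity * m >= 0:
        return ts[i_m]
    return ts[i_m] - seg[i_m] / m


def extract_biomarkers(
    ecg: ECGRecording,
    qrs_onset: float = 0.0,
    qrs_end: float = 100.0,
    t_end_method: str = "tangent",
) -> Biomarkers:
    """Lead-averaged QT, Tpe, T amplitude/polarity and QRS duration.

    The T peak is the extremum of largest absolute amplitude after ``qrs_end``
    and the T end is found by the maximum-slope tangent method (or a 5%
    amplitude threshold with ``t_end_method='threshold'``).
    """
    t = ecg.times
    post = t > qrs_end
    if not post.any():
        raise InvalidArgumentError("trace too short to contain a T wave")
    qt_per, tpe_per, amp_per, pol_per, tpeak_per = [], [], [], [], []
    global_amp = np.abs(ecg.data).max()
    for row in ecg.data:
        seg = row[post]
        if np.abs(seg).max() <= 1e-6 * max(global_amp, 1e-30):
            raise DegenerateSignalError("flat post-QRS signal: no T wave")
        i_loc = int(np.argmax(np.abs(seg)))
        i_peak = np.nonzero(post)[0][0] + i_loc
        amp = row[i_peak]
        pol = 1.0 if amp >= 0 else -1.0
        if t_end_method == "tangent":
            t_end = _t_end_tangent(t, row, i_peak, pol)
        elif t_end_method == "threshold":
            # end of electrical activity: last excursion above 5% of the T peak
            above = np.abs(row[i_peak:]) >= 0.05 * abs(amp)
            t_end = t[i_peak + int(np.nonzero(above)[0][-1])]
        else:
            raise InvalidArgumentError(f"unknown t_end_method {t_end_method!r}")
        qt_per.append(t_end - qrs_onset)
        tpe_per.append(t_end - t[i_peak])
        amp_per.append(abs(amp))
        pol_per.append(pol)
        tpeak_per.append(t[i_peak])
    qrs_mask = (t >= qrs_onset) & (t <= qrs_end)
    env = np.abs(ecg.data[:, qrs_mask]).max(axis=0)
    above = env >= 0.05 * env.max() if env.max() > 0 else np.zeros_like(env, bool)
    qrs_dur = (
        t[qrs_mask][np.nonzero(above)[0][-1]] - qrs_onset if above.any() else 0.0
    )
    i3 = ecg.lead_names.index("V3") if "V3" in ecg.lead_names else None
    i5 = ecg.lead_names.index("V5") if "V5" in ecg.lead_names else None
    disp = abs(tpeak_per[i5] - tpeak_per[i3]) if i3 is not None and i5 is not None else np.nan
    qt = float(np.mean(qt_per))
    return Biomarkers(
        qt=qt,
        qtc=qtc_fridericia(qt, ecg.rr),
        tpe=float(np.mean(tpe_per)),
        t_amplitude=float(np.mean(amp_per)),
        t_polarity=np.array(pol_per),
        qrs_duration=float(qrs_dur),
        tpeak_dispersion_v3_v5=float(disp),
    )


# ---------------------------------------------------------------------------
# Discrepancy
# ---------------------------------------------------------------------------


def _pcc(a, b):
    sa, sb = a.std(), b.std()
    if sa <= 1e-300 or sb <= 1e-300:
        warnings.warn("zero-variance lead: PCC treated as 0", stacklevel=3)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def discrepancy(
    sim: ECGRecording,
    target: ECGRecording,
    cfg: DiscrepancyConfig = DiscrepancyConfig(),
) -> float:
    """Morphology-weighted ECG mismatch.

    ``eps = mean_i [ w_p (1 - PCC_i)^2 + w_r RMSE_i / max|R_target| ]`` over
    the 8 independent leads; the RMSE normaliser is the maximum absolute
    R-wave amplitude across all target leads.
    """
    if sim.lead_names != target.lead_names:
        raise InvalidArgumentError("lead sets differ")
    a, b = sim.data, target.data
    if a.shape[1] != b.shape[1]:
        # resample target onto the simulated time base
        tt = target.times
        ts = sim.times
        b = np.stack([np.interp(ts, tt, row) for row in b])
    max_r = np.abs(b).max()
    if max_r <= 0:
        raise DegenerateSignalError("target recording is identically zero")
    terms = []
    for i in range(a.shape[0]):
        pcc = _pcc(a[i], b[i])
        rmse = float(np.sqrt(np.mean((a[i] - b[i]) ** 2)))
        terms.append(cfg.w_p * (1.0 - pcc) ** 2 + cfg.w_r * rmse / max_r)
    return float(np.mean(terms))


def lead_pcc(sim: ECGRecording, target: ECGRecording):
    """Per-lead Pearson correlation coefficients."""
    if sim.data.shape != target.data.shape:
        raise InvalidArgumentError("recordings must share shape")
    return np.array([_pcc(sim.data[i], target.data[i]) for i in range(sim.data.shape[0])])


def lead_rmse(sim: ECGRecording, target: ECGRecording):
    """Per-lead root-mean-square errors."""
    return np.sqrt(np.mean((sim.data - target.data) ** 2, axis=1))
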