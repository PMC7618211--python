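"""Ionic cell model, diffusive stimulus current, APD lookup table and drug block.

The bundled ionic model is a human-ventricular-class surrogate derived from the
Beeler-Reuter formulation, modified in two ways that matter for this pipeline:

* the time-dependent delayed-rectifier potassium current is split into an
  explicit rapid component (IKr, gate ``xr``, hERG-like, the dofetilide target)
  and a slow component (IKs, gate ``xs``), each with its own conductance
  scaler, so that APD can be controlled through gKs while IKr block prolongs
  repolarisation;
* the sodium activation gate is shifted by +10 mV so that the biphasic
  diffusive stimulus current (the median diffusion term extracted from a
  monodomain simulation, parameterised as a difference of two Gaussians) is
  able to elicit the upstroke, as it does for biophysically detailed human
  models.

All kernels integrate with Rush-Larsen gate updates and forward-Euler voltage
and calcium updates at a fixed 0.02 ms step; gate-update coefficients are
pre-tabulated against membrane voltage so the same tables serve single-cell
pacing and the tissue-scale monodomain reaction operator.

Units: time ms, voltage mV, currents uA/uF (Cm = 1 uF/cm2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from numba import njit

from .errors import (
    CoverageError,
    InvalidArgumentError,
    NotAnActionPotentialError,
    NumericalInstabilityError,
    TruncatedTraceError,
)

# ---------------------------------------------------------------------------
# Diffusive stimulus current
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdiffParams:
    """Two-Gaussian parameterisation of the diffusive stimulus current."""

    A1: float = 25.83   # uA/uF
    A2: float = 27.42   # uA/uF
    mu1: float = 13.9   # ms
    mu2: float = 14.9   # ms
    sigma1: float = 0.406   # ms
    sigma2: float = 0.4432  # ms

    def __post_init__(self):
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InvalidArgumentError("Gaussian widths must be positive")

    def as_array(self):
        return np.array(
            [self.A1, self.A2, self.mu1, self.mu2, self.sigma1, self.sigma2]
        )


#: Fit of the median diffusive current extracted from a fine-resolution
#: biventricular monodomain simulation.
DEFAULT_IDIFF = IdiffParams()


def idiff(t, params: IdiffParams = DEFAULT_IDIFF):
    """Diffusive stimulus current (uA/uF) at time ``t`` ms after beat onset."""
    t = np.asarray(t, dtype=float)
    a = params.A1 * np.exp(-((t - params.mu1) ** 2) / (2 * params.sigma1**2))
    b = params.A2 * np.exp(-((t - params.mu2) ** 2) / (2 * params.sigma2**2))
    return a - b


# ---------------------------------------------------------------------------
# Cell model parameters
# ---------------------------------------------------------------------------


@dataclass
class CellModelParams:
    """Configuration of the bundled ventricular cell model.

    ``modified_baseline`` applies the pipeline's baseline modifications that
    widen the APD range controllable through gKs: baseline gKs x5, gKr x0.5
    and a faster L-type activation time constant (tau_jca 75 -> 60 ms).
    ``gKs_scale``/``gKr_scale`` multiply the (possibly modified) baselines.
    """

    model: str = "mbr-split-k"
    gKs_scale: float = 1.0
    gKr_scale: float = 1.0
    tau_jca: float | None = None  # ms; None = 60 if modified else 75
    cycle_length: float = 800.0  # ms
    modified_baseline: bool = True
    scalers: dict = field(default_factory=dict)  # other named currents

    def __post_init__(self):
        if self.gKs_scale <= 0 or self.gKr_scale <= 0:
            raise InvalidArgumentError("conductance scalers must be positive")
        if self.cycle_length <= 0:
            raise InvalidArgumentError("cycle length must be positive")

    @property
    def tau_jca_effective(self) -> float:
        if self.tau_jca is not None:
            return self.tau_jca
        return 60.0 if self.modified_baseline else 75.0

    def effective_conductances(self):
        """(gKs, gKr, d-gate rate scale) actually used by the kernels."""
        gks = _GKS_WEIGHT * self.gKs_scale * (5.0 if self.modified_baseline else 1.0)
        gkr = _GKR_WEIGHT * self.gKr_scale * (0.5 if self.modified_baseline else 1.0)
        dscale = 75.0 / self.tau_jca_effective
        return gks, gkr, dscale

    def to_json(self):
        return json.dumps(
            {
                "model": self.model,
                "gKs_scale": self.gKs_scale,
                "gKr_scale": self.gKr_scale,
                "tau_jca": self.tau_jca,
                "cycle_length": self.cycle_length,
                "modified_baseline": self.modified_baseline,
                "scalers": self.scalers,
            }
        )

    @classmethod
    def from_json(cls, s):
        return cls(**json.loads(s))


# split of the delayed-rectifier driving function between rapid/slow components
_GKR_WEIGHT = 0.5
_GKS_WEIGHT = 0.5
_KR_SPEED = 2.5   # xr gate rate multiplier (rapid)
_KS_SPEED = 0.4   # xs gate rate multiplier (slow)
_M_SHIFT = 10.0   # mV shift of sodium activation (excitability for I_diff)

#: resting state of the bundled model: V, m, h, j, d, f, xr, xs, Cai
RESTING_STATE = np.array(
    [-84.6, 0.011, 0.988, 0.975, 0.003, 0.994, 1e-4, 1e-4, 1e-7]
)

N_STATE = 9
DT_DEFAULT = 0.02  # ms

# voltage grid for the rate tables
_VMIN, _VMAX, _NV = -150.0, 100.0, 5001
_DV = (_VMAX - _VMIN) / (_NV - 1)


def _rate_constants(V):
    """Voltage-dependent gate rates (1/ms) of the bundled model (vectorised)."""
    V = np.asarray(V, dtype=float)
    a_x1 = 0.0005 * np.exp(0.083 * (V + 50)) / (np.exp(0.057 * (V + 50)) + 1)
    b_x1 = 0.0013 * np.exp(-0.06 * (V + 20)) / (np.exp(-0.04 * (V + 20)) + 1)
    Vm = V + _M_SHIFT
    vm47 = Vm + 47.0
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        a_m = np.where(
            np.abs(vm47) < 1e-7, 10.0, -vm47 / (np.exp(-0.1 * vm47) - 1)
        )
    b_m = 40 * np.exp(-0.056 * (Vm + 72))
    a_h = 0.126 * np.exp(-0.25 * (V + 77))
    b_h = 1.7 / (np.exp(-0.082 * (V + 22.5)) + 1)
    a_j = 0.055 * np.exp(-0.25 * (V + 78)) / (np.exp(-0.2 * (V + 78)) + 1)
    b_j = 0.3 / (np.exp(-0.1 * (V + 32)) + 1)
    a_d = 0.095 * np.exp(-0.01 * (V - 5)) / (np.exp(-0.072 * (V - 5)) + 1)
    b_d = 0.07 * np.exp(-0.017 * (V + 44)) / (np.exp(0.05 * (V + 44)) + 1)
    a_f = 0.012 * np.exp(-0.008 * (V + 28)) / (np.exp(0.15 * (V + 28)) + 1)
    b_f = 0.0065 * np.exp(-0.02 * (V + 30)) / (np.exp(-0.2 * (V + 30)) + 1)
    a_xr, b_xr = a_x1 * _KR_SPEED, b_x1 * _KR_SPEED
    a_xs, b_xs = a_x1 * _KS_SPEED, b_x1 * _KS_SPEED
    return a_m, b_m, a_h, b_h, a_j, b_j, a_d, b_d, a_f, b_f, a_xr, b_xr, a_xs, b_xs


def _ik1(V):
    V = np.asarray(V, dtype=float)
    v23 = V + 23.0
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        term = np.where(
            np.abs(v23) < 1e-7, 5.0, 0.2 * v23 / (1 - np.exp(-0.04 * v23))
        )
    return 0.35 * (
        4 * (np.exp(0.04 * (V + 85)) - 1)
        / (np.exp(0.08 * (V + 53)) + np.exp(0.04 * (V + 53)))
        + term
    )


def _k_drive(V):
    """Shared delayed-rectifier driving function (uA/uF at unit gate/scale)."""
    V = np.asarray(V, dtype=float)
    return 0.8 * (np.exp(0.04 * (V + 77)) - 1) / np.exp(0.04 * (V + 35))


_TABLE_CACHE: dict = {}


def gate_tables(dt=DT_DEFAULT, dscale=1.0):
    """Pre-tabulated gate steady states / update factors and current terms.

    Returns a (16, NV) array: inf/exp(-dt/tau) pairs for gates
    m, h, j, d, f, xr, xs (in that order), then IK1(V) and the
    delayed-rectifier driving function.
    """
    key = (round(dt, 9), round(dscale, 9))
    tab = _TABLE_CACHE.get(key)
    if tab is not None:
        return tab
    V = np.linspace(_VMIN, _VMAX, _NV)
    rates = list(_rate_constants(V))
    # tau_jca modification: scale the L-type (slow inward) activation rates
    rates[6] = rates[6] * dscale  # a_d
    rates[7] = rates[7] * dscale  # b_d
    tab = np.empty((16, _NV))
    for g in range(7):
        a, b = rates[2 * g], rates[2 * g + 1]
        tab[2 * g] = a / (a + b)
        tab[2 * g + 1] = np.exp(-dt * (a + b))
    tab[14] = _ik1(V)
    tab[15] = _k_drive(V)
    _TABLE_CACHE[key] = tab
    return tab


@njit(cache=True, inline="always")
def _interp_row(tab, row, V):
    x = (V - _VMIN) / _DV
    if x <= 0.0:
        return tab[row, 0]
    if x >= _NV - 1:
        return tab[row, _NV - 1]
    i = int(x)
    f = x - i
    return tab[row, i] * (1.0 - f) + tab[row, i + 1] * f


@njit(cache=True, inline="always")
def _react(state, i, tab, gks, gkr, dt, istim):
    """One reaction step for node i of a state block (9, N). Returns dV/dt."""
    V = state[0, i]
    for g in range(7):
        inf = _interp_row(tab, 2 * g, V)
        edt = _interp_row(tab, 2 * g + 1, V)
        state[1 + g, i] = inf + (state[1 + g, i] - inf) * edt
    cai = state[8, i]
    if cai < 1e-12:
        cai = 1e-12
    Es = -82.3 - 13.0287 * np.log(cai)
    INa = (4.0 * state[1, i] ** 3 * state[2, i] * state[3, i] + 0.003) * (V - 50.0)
    Is = 0.09 * state[4, i] * state[5, i] * (V - Es)
    IK1 = _interp_row(tab, 14, V)
    drive = _interp_row(tab, 15, V)
    IK = (gkr * state[6, i] + gks * state[7, i]) * drive
    dv = -(INa + Is + IK1 + IK) + istim
    state[0, i] = V + dt * dv
    state[8, i] = cai + dt * (-1e-7 * Is + 0.07 * (1e-7 - cai))
    return dv


@njit(cache=True)
def _pace_kernel(state, tab, gks, gkr, dt, cl, n_beats, sp, out):
    """Pace a single cell; record the last beat at 1 kHz into ``out``.

    Returns the 1-based beat index at which the state diverged, or 0.
    """
    n_steps = int(round(cl / dt))
    sub = int(round(1.0 / dt))
    A1, A2, mu1, mu2, s1, s2 = sp[0], sp[1], sp[2], sp[3], sp[4], sp[5]
    for beat in range(n_beats):
        rec = beat == n_beats - 1
        for k in range(n_steps):
            if rec and k % sub == 0:
                ko = k // sub
                if ko < out.shape[0]:
                    out[ko] = state[0, 0]
            t = k * dt
            istim = A1 * np.exp(-((t - mu1) ** 2) / (2 * s1 * s1)) - A2 * np.exp(
                -((t - mu2) ** 2) / (2 * s2 * s2)
            )
            _react(state, 0, tab, gks, gkr, dt, istim)
            if not np.isfinite(state[0, 0]) or abs(state[0, 0]) > 250.0:
                return beat + 1
        if rec and out.shape[0] > n_steps // sub:
            out[n_steps // sub] = state[0, 0]
    return 0


def pace_to_steady_state(
    params: CellModelParams,
    stimulus: IdiffParams = DEFAULT_IDIFF,
    n_beats: int = 100,
    dt: float = DT_DEFAULT,
    initial_state=None,
):
    """Pace the cell for ``n_beats`` and return the last-beat trace and state.

    Returns ``(trace, state)`` where ``trace`` is the membrane potential of the
    final beat sampled at 1 kHz (cycle_length + 1 samples, t=0 at beat onset)
    and ``state`` the final state vector.
    """
    if n_beats < 1:
        raise InvalidArgumentError("n_beats must be >= 1")
    gks, gkr, dscale = params.effective_conductances()
    tab = gate_tables(dt, dscale)
    state = np.empty((N_STATE, 1))
    state[:, 0] = RESTING_STATE if initial_state is None else initial_state
    out = np.empty(int(round(params.cycle_length)) + 1)
    bad = _pace_kernel(
        state, tab, gks, gkr, dt, params.cycle_length, n_beats,
        stimulus.as_array(), out,
    )
    if bad:
        raise NumericalInstabilityError(
            f"cell state diverged during beat {bad}", beat=bad
        )
    return out, state[:, 0].copy()


# ---------------------------------------------------------------------------
# APD90
# ---------------------------------------------------------------------------


def apd90(waveform, activation_time=None):
    """APD at 90% repolarisation of a 1 kHz voltage trace, in ms.

    The upstroke reference is ``activation_time`` (ms into the trace) or, if
    omitted, the sample preceding the steepest depolarisation. APD is the time
    from the upstroke to the last crossing of
    ``U_rest + 0.1 (U_peak - U_rest)``, linearly interpolated.
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise InvalidArgumentError("waveform must be a 1-D trace")
    if w.max() - w.min() <= 20.0:
        raise NotAnActionPotentialError("trace range <= 20 mV: no upstroke")
    if activation_time is None:
        up = int(np.argmax(np.diff(w)))
    else:
        up = int(round(activation_time))
    rest = w[up]
    peak = w[up:].max()
    if peak - rest <= 20.0:
        raise NotAnActionPotentialError("no upstroke after activation time")
    level = rest + 0.1 * (peak - rest)
    seg = w[up:]
    above = np.nonzero(seg >= level)[0]
    i = int(above[-1])
    if i == seg.size - 1:
        raise TruncatedTraceError("trace ends before 90% repolarisation")
    # interpolate between the last sample at/above the level and the next one
    denom = seg[i] - seg[i + 1]
    frac = 0.0 if denom <= 0 else (seg[i] - level) / denom
    return float(i + frac)


# ---------------------------------------------------------------------------
# Lookup table
# ---------------------------------------------------------------------------

WAVEFORM_SAMPLES = 601  # 600 ms at 1000 Hz, inclusive of t=0


@dataclass
class APLookupTable:
    """Map from integer APD (ms) to gKs scaler and action-potential waveform.

    ``waveforms[k]`` holds 601 samples at 1 kHz starting at local activation
    (the upstroke), so tissue assembly can index it directly with t - t_a.
    """

    apd_values: np.ndarray        # (K,) int, strictly increasing
    gks: np.ndarray               # (K,) gKs_scale per APD, strictly decreasing
    waveforms: np.ndarray         # (K, 601)
    u_rest: float                 # mV
    cycle_length: float = 800.0

    def __post_init__(self):
        self.apd_values = np.asarray(self.apd_values, dtype=np.int64)
        self.gks = np.asarray(self.gks, dtype=float)
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if np.any(np.diff(self.apd_values) <= 0):
            raise InvalidArgumentError("apd_values must be strictly increasing")
        if self.waveforms.shape != (self.apd_values.size, WAVEFORM_SAMPLES):
            raise InvalidArgumentError(
                f"waveforms must have shape (N, {WAVEFORM_SAMPLES})"
            )

    @property
    def apd_min(self) -> int:
        return int(self.apd_values[0])

    @property
    def apd_max(self) -> int:
        return int(self.apd_values[-1])

    def key_index(self, apd):
        """Row index for integer APD key(s); raises KeyError outside range."""
        apd = np.asarray(apd)
        idx = apd - self.apd_values[0]
        if np.any(idx < 0) or np.any(idx >= self.apd_values.size):
            bad = apd[(idx < 0) | (idx >= self.apd_values.size)]
            raise KeyError(
                f"APD value(s) {np.unique(bad)} outside table range "
                f"[{self.apd_min}, {self.apd_max}] ms"
            )
        return idx

    def lookup(self, apd):
        """(gKs, waveform) for one integer APD key."""
        i = int(self.key_index(int(apd)))
        return float(self.gks[i]), self.waveforms[i]

    # -- serialisation ------------------------------------------------------

    def save(self, path):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("apd_keys", data=self.apd_values)
            fh.create_dataset("gks", data=self.gks)
            fh.create_dataset("waveforms", data=self.waveforms)
            fh.attrs["u_rest"] = self.u_rest
            fh.attrs["cycle_length"] = self.cycle_length

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as fh:
            return cls(
                apd_values=fh["apd_keys"][:],
                gks=fh["gks"][:],
                waveforms=fh["waveforms"][:],
                u_rest=float(fh.attrs["u_rest"]),
                cycle_length=float(fh.attrs["cycle_length"]),
            )

    def to_csv(self, path):
        import pandas as pd

        cols = {"apd_ms": self.apd_values, "gks_scale": self.gks}
        for k in range(WAVEFORM_SAMPLES):
            cols[f"u_{k}ms"] = self.waveforms[:, k]
        pd.DataFrame(cols).to_csv(path, index=False)


def _cell_entry(params, stimulus, gks_scale, n_beats, dt):
    """Pace one gKs sample; return (apd, waveform 601, u_rest) or None."""
    p = replace(params, gKs_scale=gks_scale)
    try:
        trace, _ = pace_to_steady_state(p, stimulus, n_beats=n_beats, dt=dt)
    except NumericalInstabilityError:
        return None
    try:
        up = int(np.argmax(np.diff(trace)))
        apd = apd90(trace)
    except (NotAnActionPotentialError, TruncatedTraceError):
        return None
    wf = np.full(WAVEFORM_SAMPLES, trace[-1])
    avail = min(WAVEFORM_SAMPLES, trace.size - up)
    wf[:avail] = trace[up : up + avail]
    return apd, wf, float(trace[:up].min() if up > 0 else trace[0])


def build_lookup(
    params: CellModelParams,
    stimulus: IdiffParams = DEFAULT_IDIFF,
    gks_fold_range=(1.0 / 50.0, 50.0),
    apd_bounds=(180.0, 310.0),
    n_beats: int = 100,
    n_initial: int = 64,
    max_refine: int = 400,
    dt: float = DT_DEFAULT,
) -> APLookupTable:
    """Build the APD -> (gKs, waveform) lookup table.

    A population of cells with gKs uniformly sampled over ``gks_fold_range``
    (multiples of the modified baseline) is paced to steady state with the
    diffusive stimulus; cells are filtered to ``apd_bounds`` and resampled to
    one entry per integer APD. Sampling is refined by bisection in gKs (APD is
    monotone decreasing in gKs) until every integer key has a waveform whose
    APD90 is within 1 ms of the key.
    """
    lo, hi = gks_fold_range
    if not lo < hi:
        raise InvalidArgumentError("gks_fold_range must be (min, max)")
    if not apd_bounds[0] < apd_bounds[1]:
        raise InvalidArgumentError("apd_bounds must be (min, max)")
    if params.cycle_length < 620.0:
        raise InvalidArgumentError(
            "cycle length too short to store a 600 ms waveform after upstroke"
        )

    samples = []  # (gks, apd, waveform, rest)
    for g in np.linspace(lo, hi, n_initial):
        ent = _cell_entry(params, stimulus, g, n_beats, dt)
        if ent is not None:
            samples.append((g, ent[0], ent[1], ent[2]))
    if not samples:
        raise CoverageError(apd_bounds, (np.nan, np.nan))
    samples.sort(key=lambda s: s[0])
    achievable = (min(s[1] for s in samples), max(s[1] for s in samples))
    if achievable[0] > apd_bounds[0] or achievable[1] < apd_bounds[1]:
        raise CoverageError(apd_bounds, achievable)

    keys = np.arange(int(np.ceil(apd_bounds[0])), int(np.floor(apd_bounds[1])) + 1)

    def nearest(k):
        return min(samples, key=lambda s: (abs(s[1] - k), s[0]))

    budget = max_refine
    for k in keys:
        # per-key secant refinement on the monotone (decreasing) APD-gKs map
        for _ in range(12):
            if budget <= 0 or abs(nearest(k)[1] - k) <= 0.5:
                break
            apds = np.array([s[1] for s in samples])
            gvals = np.array([s[0] for s in samples])
            above = apds >= k  # larger-APD side = smaller gKs
            below = apds <= k
            if not above.any() or not below.any():
                break  # key at the achievable boundary; keep nearest sample
            g_lo = gvals[above].max()
            a_lo = apds[gvals == g_lo].min()
            g_hi = gvals[below].min()
            a_hi = apds[gvals == g_hi].max()
            if g_hi - g_lo < 1e-12 or a_lo <= a_hi:
                break  # interval (or monotonicity) exhausted locally
            g_new = g_lo + (a_lo - k) * (g_hi - g_lo) / (a_lo - a_hi)
            g_new = min(max(g_new, g_lo + 0.05 * (g_hi - g_lo)),
                        g_hi - 0.05 * (g_hi - g_lo))
            ent = _cell_entry(params, stimulus, g_new, n_beats, dt)
            budget -= 1
            if ent is None:
                break
            samples.append((g_new, ent[0], ent[1], ent[2]))
        if budget <= 0:
            break
    samples.sort(key=lambda s: s[0])

    sel = [nearest(k) for k in keys]
    gks = np.array([s[0] for s in sel])
    waveforms = np.stack([s[2] for s in sel])
    u_rest = float(np.median([s[3] for s in sel]))
    # keys ascend => gKs must strictly descend (one-to-one APD<->gKs)
    if np.any(np.diff(gks) >= 0):
        # collapse duplicate selections by nudging onto the monotone hull
        for i in range(1, gks.size):
            if gks[i] >= gks[i - 1]:
                gks[i] = np.nextafter(gks[i - 1], 0.0)
    return APLookupTable(
        apd_values=keys,
        gks=gks,
        waveforms=waveforms,
        u_rest=u_rest,
        cycle_length=params.cycle_length,
    )


# ---------------------------------------------------------------------------
# Drug block
# ---------------------------------------------------------------------------


@dataclass
class DrugSpec:
    """Conductance-block drug description (Hill equation)."""

    target: str = "IKr"
    ic50: float = 1.0       # nM
    hill: float = 0.85      # dimensionless
    doses: tuple = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # nM

    def __post_init__(self):
        if self.ic50 <= 0:
            raise InvalidArgumentError("IC50 must be positive")
        if self.hill <= 0:
            raise InvalidArgumentError("Hill coefficient must be positive")
        if any(d < 0 for d in self.doses):
            raise InvalidArgumentError("doses must be non-negative")

    def to_json(self):
        return json.dumps(
            {"target": self.target, "ic50": self.ic50, "hill": self.hill,
             "doses": list(self.doses)}
        )

    @classmethod
    def from_json(cls, s):
        d = json.loads(s)
        d["doses"] = tuple(d["doses"])
        return cls(**d)


def hill_block(dose, spec: DrugSpec):
    """Remaining conductance fraction 1 / (1 + (dose/IC50)^h)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise InvalidArgumentError("dose must be non-negative")
    out = 1.0 / (1.0 + (dose / spec.ic50) ** spec.hill)
    return float(out) if out.ndim == 0 else out


def calibrate_hill(pairs):
    """Fit (IC50, h) to (dose nM, blocked fraction) pairs.

    With exactly two pairs the fit is exact (closed form on the log-linearised
    Hill equation); more pairs are fitted by least squares in log space.
    """
    pairs = [(float(d), float(b)) for d, b in pairs]
    if len(pairs) < 2:
        raise InvalidArgumentError("need at least two (dose, block) pairs")
    # block b = (d/ic50)^h / (1 + (d/ic50)^h)  =>  log(b/(1-b)) = h(log d - log ic50)
    x = np.log([d for d, _ in pairs])
    y = np.log([b / (1 - b) for _, b in pairs])
    h, c = np.polyfit(x, y, 1)
    ic50 = float(np.exp(-c / h))
    return ic50, float(h)


def dofetilide_spec(doses=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)) -> DrugSpec:
    """Dofetilide IKr-block spec calibrated to the reported block fractions.

    The published dose series 0.5..6 nM corresponds to roughly 40/50/60/66/70/
    73/76% IKr block; fitting the Hill equation to the (0.5 nM, 40%) and
    (1 nM, 50%) anchor pairs fixes IC50 and h and reproduces the remaining
    percentages to the printed precision.
    """
    ic50, h = calibrate_hill([(0.5, 0.40), (1.0, 0.50)])
    return DrugSpec(target="IKr", ic50=ic50, hill=h, doses=tuple(doses))


def repace_table_with_params(
    table: APLookupTable,
    params: CellModelParams,
    stimulus: IdiffParams = DEFAULT_IDIFF,
    n_beats: int = 100,
    dt: float = DT_DEFAULT,
) -> APLookupTable:
    """Re-pace every table entry at its stored gKs under modified cell params.

    Used for drug evaluation: the spatial gKs field inferred at baseline is
    kept fixed (same keys, same gKs column) while the waveforms are
    re-simulated with, e.g., a blocked gKr - so the stored waveform APDs no
    longer equal the nominal keys, which is exactly the drug effect.
    """
    waveforms = np.empty_like(table.waveforms)
    rests = []
    for k, g in enumerate(table.gks):
        ent = _cell_entry(params, stimulus, g, n_beats, dt)
        if ent is None:
            raise NumericalInstabilityError(
                f"re-pacing failed for gKs={g:.4g}", beat=None
            )
        waveforms[k] = ent[1]
        rests.append(ent[2])
    return APLookupTable(
        apd_values=table.apd_values.copy(),
        gks=table.gks.copy(),
        waveforms=waveforms,
        u_rest=float(np.median(rests)),
        cycle_length=params.cycle_length,
    )


_TARGET_MAP = {"IKr": "gKr_scale", "IKs": "gKs_scale"}


def apply_drug(params: CellModelParams, spec: DrugSpec, dose) -> CellModelParams:
    """Return params with the target conductance scaled by the Hill block."""
    attr = _TARGET_MAP.get(spec.target)
    if attr is None:
        raise InvalidArgumentError(
            f"unknown target current {spec.target!r}; known: {sorted(_TARGET_MAP)}"
        )
    factor = hill_block(dose, spec)
    return replace(params, **{attr: getattr(params, attr) * factor})
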