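"""Reference monodomain solver, conductivity calibration and RE translation.

The solver is a structured-grid finite-difference monodomain integrator with
Godunov operator splitting: a Rush-Larsen reaction sub-step (shared gate
tables with the single-cell kernels) followed by an explicit anisotropic
diffusion sub-step with no-flux boundaries. It is intended for cable and slab
domains - conductivity calibration, diffusive-current extraction and
desk-scale translation experiments - not whole-organ runs.

Axes are aligned with the (fibre, sheet, normal) directions, i.e. slabs are
simulated with zero fibre rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from . import cells
from .cells import CellModelParams, IdiffParams, gate_tables, _react
from .eikonal import ConductionSpeeds, RootNodes
from .errors import CalibrationError, InvalidArgumentError, NumericalInstabilityError
from .geometry import Mesh, generate_slab
from .re_model import VmSolution

ACT_THRESHOLD = -20.0  # mV upstroke-crossing level for activation times


@dataclass
class Conductivities:
    """Orthotropic monodomain conductivities and membrane constants."""

    sigma_f: float = 1.5   # mS/cm
    sigma_s: float = 0.8
    sigma_n: float = 0.8
    chi: float = 1400.0    # cm^-1
    cm: float = 1.0        # uF/cm^2

    def __post_init__(self):
        for name in ("sigma_f", "sigma_s", "sigma_n", "chi", "cm"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    def diffusivities_mm2_ms(self):
        """(Df, Ds, Dn) in mm^2/ms: sigma / (chi * Cm), converted."""
        return 100.0 * np.array([self.sigma_f, self.sigma_s, self.sigma_n]) / (
            self.chi * self.cm
        )


@dataclass
class Grid:
    """Regular structured grid, x-fastest node ordering (matches slab meshes)."""

    nx: int
    ny: int
    nz: int
    spacing: float  # mm

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1 or self.spacing <= 0:
            raise InvalidArgumentError("grid dimensions must be positive")

    @property
    def n_nodes(self):
        return self.nx * self.ny * self.nz

    @property
    def positions(self):
        zs, ys, xs = np.meshgrid(
            np.arange(self.nz), np.arange(self.ny), np.arange(self.nx),
            indexing="ij",
        )
        return (
            np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]) * self.spacing
        )

    def to_mesh(self, fibre_angle=0.0) -> Mesh:
        return generate_slab(self.nx, self.ny, self.nz, self.spacing, fibre_angle)


def grid_from_slab_mesh(mesh: Mesh) -> Grid:
    """Recover the structured grid of a mesh produced by ``generate_slab``."""
    xs = np.unique(mesh.nodes[:, 0])
    ys = np.unique(mesh.nodes[:, 1])
    zs = np.unique(mesh.nodes[:, 2])
    h = xs[1] - xs[0]
    for arr in (xs, ys, zs):
        if arr.size > 1 and not np.allclose(np.diff(arr), h, atol=1e-9):
            raise InvalidArgumentError("mesh is not a regular slab grid")
    if xs.size * ys.size * zs.size != mesh.n_nodes:
        raise InvalidArgumentError("mesh is not a full structured grid")
    return Grid(xs.size, ys.size, zs.size, float(h))


@dataclass
class MonodomainConfig:
    """Numerical and stimulus configuration of a monodomain run."""

    duration: float          # ms
    dt: float = 0.02         # ms
    stim_nodes: np.ndarray = field(default_factory=lambda: np.array([0]))
    stim_times: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    stim_amplitude: float = 60.0  # uA/uF
    stim_duration: float = 2.0    # ms

    def __post_init__(self):
        self.stim_nodes = np.asarray(self.stim_nodes, dtype=np.int64)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidArgumentError("duration and dt must be positive")
        if self.stim_nodes.size != self.stim_times.size:
            raise InvalidArgumentError("stimulus nodes and times must align")


@dataclass
class MonodomainResult:
    vm: VmSolution
    activation_times: np.ndarray            # ms; -1 where never activated
    diffusion_current: np.ndarray | None    # (frames, N) uA/uF, if stored


@njit(cache=True)
def _mono_kernel(
    state, tab, gks, gkr, nx, ny, nz, Dx, Dy, Dz, h, dt, n_steps,
    stim_start, stim_amp, stim_dur, sub, out_v, out_d, store_diff,
    act_time, stop_node,
):
    n = nx * ny * nz
    lap = np.empty(n)
    h2 = h * h
    for k in range(n_steps):
        t = k * dt
        if k % sub == 0:
            fr = k // sub
            if fr < out_v.shape[0]:
                for i in range(n):
                    out_v[fr, i] = state[0, i]
        # reaction sub-step (pointwise)
        for i in range(n):
            istim = 0.0
            s0 = stim_start[i]
            if s0 >= 0.0 and s0 <= t < s0 + stim_dur:
                istim = stim_amp
            vold = state[0, i]
            _react(state, i, tab, gks[i], gkr, dt, istim)
            vnew = state[0, i]
            if act_time[i] < 0.0 and vold < ACT_THRESHOLD <= vnew:
                act_time[i] = t + dt * (ACT_THRESHOLD - vold) / (vnew - vold)
            if not np.isfinite(vnew) or abs(vnew) > 250.0:
                return k + 1
        # diffusion sub-step; zero-flux boundary faces (finite-volume form:
        # the boundary ghost equals the node itself, so the discrete
        # Laplacian telescopes to the boundary fluxes, which vanish)
        for iz in range(nz):
            for iy in range(ny):
                base = nx * (iy + ny * iz)
                for ix in range(nx):
                    i = ix + base
                    v = state[0, i]
                    acc = 0.0
                    if nx > 1:
                        vl = state[0, i - 1] if ix > 0 else v
                        vr = state[0, i + 1] if ix < nx - 1 else v
                        acc += Dx * (vl + vr - 2.0 * v)
                    if ny > 1:
                        vl = state[0, i - nx] if iy > 0 else v
                        vr = state[0, i + nx] if iy < ny - 1 else v
                        acc += Dy * (vl + vr - 2.0 * v)
                    if nz > 1:
                        s2 = nx * ny
                        vl = state[0, i - s2] if iz > 0 else v
                        vr = state[0, i + s2] if iz < nz - 1 else v
                        acc += Dz * (vl + vr - 2.0 * v)
                    lap[i] = acc / h2
        for i in range(n):
            state[0, i] += dt * lap[i]
        if store_diff and k % sub == 0:
            fr = k // sub
            if fr < out_d.shape[0]:
                for i in range(n):
                    out_d[fr, i] = lap[i]
        if stop_node >= 0 and act_time[stop_node] >= 0.0 and t > act_time[stop_node] + 5.0:
            return 0
    return 0


def solve_monodomain(
    grid,
    cond: Conductivities,
    cell: CellModelParams,
    cfg: MonodomainConfig,
    gks_scale_field=None,
    store_diffusion: bool = False,
    initial_state=None,
    _stop_node: int = -1,
) -> MonodomainResult:
    """Operator-split monodomain run on a structured grid (or slab mesh)."""
    if isinstance(grid, Mesh):
        grid = grid_from_slab_mesh(grid)
    n = grid.n_nodes
    D = cond.diffusivities_mm2_ms()
    # explicit-diffusion stability bound
    dims = np.array([grid.nx > 1, grid.ny > 1, grid.nz > 1], dtype=float)
    dsum = float(np.sum(D * dims))
    if dsum > 0 and cfg.dt > grid.spacing**2 / (2.0 * dsum):
        raise InvalidArgumentError(
            f"dt={cfg.dt} ms violates the diffusion stability bound "
            f"{grid.spacing ** 2 / (2 * dsum):.4g} ms"
        )
    if np.any(cfg.stim_nodes < 0) or np.any(cfg.stim_nodes >= n):
        raise InvalidArgumentError("stimulus node outside the domain")
    gks_eff, gkr_eff, dscale = cell.effective_conductances()
    if gks_scale_field is None:
        gks = np.full(n, gks_eff)
    else:
        gks_scale_field = np.asarray(gks_scale_field, dtype=float)
        if gks_scale_field.shape != (n,):
            raise InvalidArgumentError("gks_scale_field must have one value per node")
        gks = (gks_eff / cell.gKs_scale) * gks_scale_field
    tab = gate_tables(cfg.dt, dscale)
    state = np.empty((cells.N_STATE, n))
    state[:] = (
        cells.RESTING_STATE[:, None] if initial_state is None else initial_state
    )
    stim_start = np.full(n, -1.0)
    stim_start[cfg.stim_nodes] = cfg.stim_times
    n_steps = int(round(cfg.duration / cfg.dt))
    sub = int(round(1.0 / cfg.dt))  # 1 kHz frames
    n_frames = n_steps // sub + 1
    out_v = np.zeros((n_frames, n))
    out_d = np.zeros((n_frames if store_diffusion else 1, n if store_diffusion else 1))
    act = np.full(n, -1.0)
    bad = _mono_kernel(
        state, tab, gks, gkr_eff, grid.nx, grid.ny, grid.nz,
        D[0], D[1], D[2], grid.spacing, cfg.dt, n_steps,
        stim_start, cfg.stim_amplitude, cfg.stim_duration, sub,
        out_v, out_d, store_diffusion, act, _stop_node,
    )
    if bad:
        raise NumericalInstabilityError(
            f"monodomain state diverged at step {bad}", step=bad
        )
    out_v[-1] = state[0]
    vm = VmSolution(out_v.T.copy(), rate=1000.0, duration=float(n_frames - 1))
    return MonodomainResult(
        vm=vm,
        activation_times=act,
        diffusion_current=out_d if store_diffusion else None,
    )


# ---------------------------------------------------------------------------
# Conductivity calibration
# ---------------------------------------------------------------------------

_SIGMA_ATTR = {"fibre": "sigma_f", "sheet": "sigma_s", "normal": "sigma_n"}


def measure_cable_cv(
    sigma: float,
    cell: CellModelParams,
    length: float = 80.0,
    h: float = 0.125,
    chi: float = 1400.0,
    cm: float = 1.0,
    dt: float = 0.01,
) -> float:
    """Conduction velocity (cm/s) in a 1-D cable with conductivity ``sigma``.

    CV is measured between two interior probes >= 10 mm apart inside the
    middle third of the cable, from threshold-crossing activation times.
    """
    nx = int(round(length / h)) + 1
    grid = Grid(nx, 1, 1, h)
    cond = Conductivities(sigma_f=sigma, sigma_s=sigma, sigma_n=sigma, chi=chi, cm=cm)
    n_stim = max(2, int(round(2.0 / h)))
    p1 = int(round(0.4 * (nx - 1)))
    p2 = int(round(0.6 * (nx - 1)))
    cfg = MonodomainConfig(
        duration=400.0,
        dt=dt,
        stim_nodes=np.arange(n_stim),
        stim_times=np.zeros(n_stim),
    )
    res = solve_monodomain(grid, cond, cell, cfg, _stop_node=p2)
    t1, t2 = res.activation_times[p1], res.activation_times[p2]
    if t1 < 0 or t2 < 0 or t2 <= t1:
        raise CalibrationError(
            f"wave failed to propagate across the cable (sigma={sigma})"
        )
    return float((p2 - p1) * h / (t2 - t1) * 100.0)  # mm/ms -> cm/s


def calibrate_conductivity(
    target_cv: float,
    direction: str = "fibre",
    cell: CellModelParams | None = None,
    length: float = 80.0,
    h: float = 0.125,
    chi: float = 1400.0,
    cm: float = 1.0,
    rel_tol: float = 0.003,
    max_iter: int = 30,
    dt: float = 0.01,
) -> dict:
    """Bisection calibration of one conductivity to a target CV.

    Returns ``{"direction", "target_cv", "sigma", "measured_cv"}``; the
    returned ``measured_cv`` comes from an independent re-measurement with the
    calibrated sigma.
    """
    if target_cv <= 0:
        raise InvalidArgumentError("target_cv must be positive")
    if direction not in _SIGMA_ATTR:
        raise InvalidArgumentError(f"direction must be one of {sorted(_SIGMA_ATTR)}")
    cell = cell if cell is not None else CellModelParams()

    def f(sig):
        return measure_cable_cv(sig, cell, length, h, chi, cm, dt)

    # cable theory: CV ~ sqrt(sigma); jump near the target, then bracket
    sig = 1.0
    cv = f(sig)
    sig = sig * (target_cv / cv) ** 2
    lo, hi = sig / 1.5, sig * 1.5
    cv_lo, cv_hi = f(lo), f(hi)
    widen = 0
    while not (cv_lo < target_cv < cv_hi):
        widen += 1
        if widen > 8:
            raise CalibrationError(
                f"could not bracket target CV {target_cv} cm/s "
                f"(last bracket [{cv_lo:.1f}, {cv_hi:.1f}] cm/s)"
            )
        if cv_lo >= target_cv:
            lo /= 2.0
            cv_lo = f(lo)
        if cv_hi <= target_cv:
            hi *= 2.0
            cv_hi = f(hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cv = f(mid)
        if abs(cv - target_cv) <= rel_tol * target_cv:
            break
        if cv < target_cv:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
    measured = measure_cable_cv(mid, cell, length, h, chi, cm, dt)
    return {
        "direction": direction,
        "target_cv": float(target_cv),
        "sigma": float(mid),
        "measured_cv": float(measured),
    }


# ---------------------------------------------------------------------------
# RE -> monodomain translation
# ---------------------------------------------------------------------------


def closest_point_map(coarse_positions, fine_positions, tie_tol=1e-9):
    """Index of the closest coarse node per fine node (lowest index on ties)."""
    coarse_positions = np.asarray(coarse_positions, dtype=float)
    fine_positions = np.asarray(fine_positions, dtype=float)
    if fine_positions.size == 0:
        raise InvalidArgumentError("empty fine point set")
    tree = cKDTree(coarse_positions)
    k = min(4, coarse_positions.shape[0])
    dist, idx = tree.query(fine_positions, k=k)
    if k == 1:
        return np.atleast_1d(idx)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    tied = dist <= dist[:, [0]] + tie_tol
    masked = np.where(tied, idx, np.iinfo(np.int64).max)
    return masked.min(axis=1)


@dataclass
class MonodomainSetup:
    """Everything needed to run the translated monodomain simulation."""

    grid: Grid
    conductivities: Conductivities
    gks_scale_field: np.ndarray
    cell: CellModelParams
    stim_nodes: np.ndarray
    stim_times: np.ndarray
    coarse_to_fine: np.ndarray


def translate_re_to_monodomain(
    coarse_mesh: Mesh,
    apd,
    table,
    speeds: ConductionSpeeds,
    roots: RootNodes,
    cell: CellModelParams,
    fine,
    chi: float = 1400.0,
    cm: float = 1.0,
    stim_radius: float = 1.0,
    calibration=None,
    calibration_h: float | None = None,
    calibration_dt: float = 0.02,
) -> MonodomainSetup:
    """Translate an RE configuration onto a finer structured grid.

    gKs scalers come from the lookup table applied to the coarse APD field and
    are mapped by closest-point interpolation; conductivities are calibrated
    per direction to the RE conduction speeds (pass ``calibration`` as a dict
    ``{"fibre": sigma, ...}`` to reuse earlier calibrations); stimulus sites
    are the fine nodes within ``stim_radius`` mm of each RE root node, with
    the root's activation-time offset.
    """
    if isinstance(fine, Mesh):
        fine_grid = grid_from_slab_mesh(fine)
        fine_pos = fine.nodes
    else:
        fine_grid = fine
        fine_pos = fine.positions
    if fine_grid.n_nodes == 0:
        raise InvalidArgumentError("empty fine mesh")
    apd = np.asarray(apd)
    gks_coarse = table.gks[table.key_index(apd)]
    c2f = closest_point_map(coarse_mesh.nodes, fine_pos)
    gks_fine = gks_coarse[c2f]

    if calibration is None:
        calibration = {}
    sig = {}
    for direction, target in (
        ("fibre", speeds.Vf), ("sheet", speeds.Vs), ("normal", speeds.Vn)
    ):
        if direction in calibration:
            sig[direction] = calibration[direction]
        else:
            sig[direction] = calibrate_conductivity(
                target, direction, cell, chi=chi, cm=cm,
                h=calibration_h if calibration_h is not None else fine_grid.spacing,
                dt=calibration_dt,
            )["sigma"]
    cond = Conductivities(
        sigma_f=sig["fibre"], sigma_s=sig["sheet"], sigma_n=sig["normal"],
        chi=chi, cm=cm,
    )
    stim_nodes, stim_times = [], []
    tree = cKDTree(fine_pos)
    for root_idx, offset in zip(roots.indices, roots.offsets):
        ball = tree.query_ball_point(coarse_mesh.nodes[root_idx], stim_radius)
        if not ball:
            ball = [int(closest_point_map(fine_pos, coarse_mesh.nodes[[root_idx]])[0])]
        stim_nodes.extend(ball)
        stim_times.extend([offset] * len(ball))
    stim_nodes = np.asarray(stim_nodes, dtype=np.int64)
    stim_times = np.asarray(stim_times, dtype=float)
    uniq, first = np.unique(stim_nodes, return_index=True)
    return MonodomainSetup(
        grid=fine_grid,
        conductivities=cond,
        gks_scale_field=gks_fine,
        cell=cell,
        stim_nodes=uniq,
        stim_times=stim_times[first],
        coarse_to_fine=c2f,
    )


# ---------------------------------------------------------------------------
# Diffusive-current extraction
# ---------------------------------------------------------------------------

IDIFF_ALIGN_OFFSET = 14.0  # ms: aligned local activation sits here in the window


def extract_median_idiff(result: MonodomainResult, window=(0.0, 100.0)):
    """Median activation-aligned diffusive current and its two-Gaussian fit.

    Returns ``(times, median_trace, params, converged)``. Requires a run with
    ``store_diffusion=True``.
    """
    if result.diffusion_current is None:
        raise InvalidArgumentError(
            "monodomain run must store the diffusion term (store_diffusion=True)"
        )
    D = result.diffusion_current  # (frames, N)
    act = result.activation_times
    taus = np.arange(int(window[0]), int(window[1]) + 1, dtype=float)
    nodes = np.nonzero(act >= 0)[0]
    if nodes.size == 0:
        raise InvalidArgumentError("no activated nodes in the solution")
    traces = np.zeros((nodes.size, taus.size))
    for row, i in enumerate(nodes):
        src = np.rint(act[i] - IDIFF_ALIGN_OFFSET + taus).astype(np.int64)
        ok = (src >= 0) & (src < D.shape[0])
        traces[row, ok] = D[src[ok], i]
    median = np.median(traces, axis=0)

    def model(t, a1, a2, m1, m2, s1, s2):
        return a1 * np.exp(-((t - m1) ** 2) / (2 * s1**2)) - a2 * np.exp(
            -((t - m2) ** 2) / (2 * s2**2)
        )

    i_max, i_min = int(np.argmax(median)), int(np.argmin(median))
    p0 = [
        max(median.max(), 1e-3), max(-median.min(), 1e-3),
        taus[i_max], taus[i_min], 0.5, 0.5,
    ]
    try:
        popt, _ = curve_fit(
            model, taus, median, p0=p0,
            bounds=([0, 0, window[0], window[0], 1e-3, 1e-3],
                    [np.inf, np.inf, window[1], window[1], 50, 50]),
            maxfev=20000,
        )
        params = IdiffParams(*popt)
        converged = True
    except (RuntimeError, ValueError):
        params, converged = None, False
    return taus, median, params, converged
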