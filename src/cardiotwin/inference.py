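"""SMC-ABC inference over discretised parameter lattices and Sobol sensitivity.

The sequential Monte Carlo approximate Bayesian computation variant here is a
drop-and-replenish sampler with an adaptive threshold: each iteration discards
the worst fraction of the particle population by ECG discrepancy, sets the
threshold to the surviving maximum, and refills the discarded slots with
Metropolis resample-move proposals constrained to the parameter lattice
(per-parameter random-walk widths adapted to the surviving population's
spread). Termination: threshold below the target cut-off, population
uniqueness below the uniqueness threshold, or the iteration cap.

Sobol sensitivity uses a Saltelli design on a scrambled Sobol sequence with
the Saltelli-2010 first-order and Jansen total-order estimators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .ecg import DiscrepancyConfig, ECGRecording, discrepancy
from .eikonal import ConductionSpeeds, RootNodes, solve_activation
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parameter:
    name: str
    lo: float
    hi: float
    resolution: float
    kind: str = "repolarisation"  # or "activation"

    def __post_init__(self):
        if self.resolution <= 0:
            raise InvalidArgumentError("resolution must be positive")
        if not self.lo <= self.hi:
            raise InvalidArgumentError("bounds must be ordered")

    @property
    def n_levels(self):
        return int(round((self.hi - self.lo) / self.resolution)) + 1

    def snap(self, value):
        k = np.rint((np.asarray(value, float) - self.lo) / self.resolution)
        return np.clip(self.lo + k * self.resolution, self.lo, self.hi)


@dataclass
class ParameterSpace:
    parameters: list

    def __post_init__(self):
        if not self.parameters:
            raise InvalidArgumentError("empty parameter space")

    @property
    def names(self):
        return [p.name for p in self.parameters]

    @property
    def dim(self):
        return len(self.parameters)

    def sample(self, rng, n):
        """Uniform lattice samples, shape (n, dim)."""
        cols = []
        for p in self.parameters:
            levels = rng.integers(0, p.n_levels, size=n)
            cols.append(p.lo + levels * p.resolution)
        return np.column_stack(cols)

    def snap(self, theta):
        theta = np.atleast_2d(np.asarray(theta, float))
        out = np.column_stack(
            [p.snap(theta[:, j]) for j, p in enumerate(self.parameters)]
        )
        return out

    def as_dict(self, theta):
        return dict(zip(self.names, np.asarray(theta, float)))


def repolarisation_space(
    gradient_bounds=(-1.0, 1.0),
    apd_min_bounds=(180.0, 230.0),
    apd_max_bounds=(270.0, 300.0),
    gradient_resolution=0.1,
    apd_resolution=2.0,
) -> ParameterSpace:
    """The six-parameter APD-field space with its standard discretisation."""
    g = gradient_bounds
    return ParameterSpace(
        [
            Parameter("g_ab", g[0], g[1], gradient_resolution),
            Parameter("g_tm", g[0], g[1], gradient_resolution),
            Parameter("g_pa", g[0], g[1], gradient_resolution),
            Parameter("g_tv", g[0], g[1], gradient_resolution),
            Parameter("apd_min", *apd_min_bounds, apd_resolution),
            Parameter("apd_max", *apd_max_bounds, apd_resolution),
        ]
    )


# ---------------------------------------------------------------------------
# SMC-ABC
# ---------------------------------------------------------------------------


@dataclass
class SMCConfig:
    population: int = 120
    sampling_rate: float = 0.5        # fraction replaced per iteration
    cutoff: float = 0.5               # target discrepancy
    uniqueness_threshold: float = 0.5  # stop when unique fraction drops below
    max_iterations: int = 40
    n_moves: int = 3                  # Metropolis moves per replenished particle
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise InvalidArgumentError("population must be >= 2")
        for frac in (self.sampling_rate, self.uniqueness_threshold):
            if not 0 < frac <= 1:
                raise InvalidArgumentError("fractions must be in (0, 1]")


@dataclass
class ParticlePopulation:
    """Final particle set with discrepancies and iteration history."""

    space: ParameterSpace
    theta: np.ndarray        # (N, dim), on the lattice
    eps: np.ndarray          # (N,)
    history: list = field(default_factory=list)  # (iteration, threshold, acc_rate)
    ecgs: np.ndarray | None = None  # (N, leads, T) per-particle simulated ECGs
    terminated_by: str = "max_iterations"

    def sorted_indices(self):
        return np.argsort(self.eps, kind="stable")

    @property
    def best(self):
        i = int(self.sorted_indices()[0])
        return self.space.as_dict(self.theta[i]), float(self.eps[i])

    def to_csv(self, path):
        df = pd.DataFrame(self.theta, columns=self.space.names)
        df["eps"] = self.eps
        df.to_csv(path, index=False)

    def save_metadata(self, path, config: SMCConfig):
        with open(path, "w") as fh:
            json.dump(
                {
                    "population": config.population,
                    "sampling_rate": config.sampling_rate,
                    "cutoff": config.cutoff,
                    "uniqueness_threshold": config.uniqueness_threshold,
                    "seed": config.seed,
                    "terminated_by": self.terminated_by,
                    "history": [
                        {"iteration": it, "threshold": th, "acceptance_rate": ar}
                        for it, th, ar in self.history
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_csv(cls, path, space: ParameterSpace):
        df = pd.read_csv(path)
        return cls(
            space=space,
            theta=df[space.names].to_numpy(),
            eps=df["eps"].to_numpy(),
        )


def uniqueness(pop) -> float:
    """Fraction of distinct lattice parameter sets in a population."""
    theta = pop.theta if isinstance(pop, ParticlePopulation) else np.asarray(pop)
    if theta.shape[0] == 0:
        raise InvalidArgumentError("empty population")
    return np.unique(theta, axis=0).shape[0] / theta.shape[0]


def _evaluate(forward, theta_row, space, target, dcfg):
    try:
        sim = forward(space.as_dict(theta_row))
    except InvalidArgumentError as exc:  # infeasible proposal (e.g. empty root set)
        logger.debug("infeasible proposal %s: %s", space.as_dict(theta_row), exc)
        return np.inf, None
    except Exception:  # forward failure: infinite discrepancy, never dropped silently
        logger.warning("forward model failed for %s", space.as_dict(theta_row), exc_info=True)
        return np.inf, None
    if isinstance(sim, ECGRecording):
        return discrepancy(sim, target, dcfg), sim
    return float(sim), None  # scalar-discrepancy toy problems


def smc_abc(
    forward,
    target,
    space: ParameterSpace,
    cfg: SMCConfig,
    discrepancy_cfg: DiscrepancyConfig | None = None,
    keep_ecgs: bool = False,
) -> ParticlePopulation:
    """Lattice-constrained SMC-ABC. ``forward`` maps a parameter dict to an
    :class:`ECGRecording` (or directly to a scalar discrepancy for toy
    problems, in which case ``target`` is ignored)."""
    dcfg = discrepancy_cfg or DiscrepancyConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population
    theta = space.sample(rng, n)
    eps = np.empty(n)
    ecgs = [None] * n
    for i in range(n):
        eps[i], ecgs[i] = _evaluate(forward, theta[i], space, target, dcfg)
    history = []
    terminated = "max_iterations"
    for it in range(1, cfg.max_iterations + 1):
        order = np.argsort(eps, kind="stable")
        n_drop = max(1, int(round(cfg.sampling_rate * n)))
        survivors = order[: n - n_drop]
        dropped = order[n - n_drop:]
        threshold = float(eps[survivors].max())
        # proposal widths from the surviving population spread (>= 1 lattice step)
        widths = []
        for j, p in enumerate(space.parameters):
            widths.append(max(np.std(theta[survivors, j]), p.resolution))
        accepted = 0
        proposed = 0
        for slot in dropped:
            src = survivors[rng.integers(survivors.size)]
            cur = theta[src].copy()
            cur_eps = eps[src]
            cur_ecg = ecgs[src]
            for _ in range(cfg.n_moves):
                prop = cur.copy()
                for j, p in enumerate(space.parameters):
                    step = rng.normal(0.0, widths[j])
                    prop[j] = p.snap(cur[j] + step)
                proposed += 1
                e_new, ecg_new = _evaluate(forward, prop, space, target, dcfg)
                if e_new <= threshold:
                    cur, cur_eps, cur_ecg = prop, e_new, ecg_new
                    accepted += 1
            theta[slot] = cur
            eps[slot] = cur_eps
            ecgs[slot] = cur_ecg
        acc_rate = accepted / max(proposed, 1)
        history.append((it, threshold, acc_rate))
        uniq = uniqueness(theta)
        if uniq < cfg.uniqueness_threshold:
            terminated = "uniqueness"
            break
        if threshold <= cfg.cutoff:
            terminated = "cutoff"
            break
    pop = ParticlePopulation(
        space=space,
        theta=space.snap(theta),
        eps=eps,
        history=history,
        terminated_by=terminated,
    )
    if keep_ecgs and all(e is not None for e in ecgs):
        pop.ecgs = np.stack([e.data for e in ecgs])
    elif keep_ecgs:
        pop.ecgs = None
    return pop


# ---------------------------------------------------------------------------
# Activation and repolarisation inference
# ---------------------------------------------------------------------------


def _qrs_trim(ecg: ECGRecording, qrs_window):
    t = ecg.times
    m = (t >= qrs_window[0]) & (t <= qrs_window[1])
    return ECGRecording(ecg.data[:, m], rate=ecg.rate, rr=ecg.rr,
                        lead_names=ecg.lead_names)


def infer_activation(
    mesh,
    candidate_roots: RootNodes,
    target_qrs: ECGRecording,
    cfg: SMCConfig,
    table,
    electrodes,
    qrs_window=(0.0, 120.0),
    fixed=None,
    speed_bounds=None,
    uniform_apd=250,
):
    """Infer (Vs, Vd, Ve) and the active subset of candidate root nodes.

    Vf, Vn and Vp stay fixed at their prescribed physiological values; the
    QRS-window pseudo-ECG of an RE run with a uniform APD field is matched
    against the target QRS. Returns ``(speeds, roots, population)`` for the
    lowest-discrepancy particle.
    """
    from .ecg import normalise_r_progression, pseudo_ecg
    from .re_model import assemble_vm

    if candidate_roots.n_root == 0:
        raise InvalidArgumentError("candidate root set must be non-empty")
    fixed = fixed or {}
    vf = fixed.get("Vf", 65.0)
    vn = fixed.get("Vn", 48.0)
    vp = fixed.get("Vp", 300.0)
    sb = speed_bounds or {"Vs": (30.0, 90.0), "Vd": (80.0, 200.0), "Ve": (50.0, 150.0)}
    params = [
        Parameter("Vs", *sb["Vs"], 1.0, kind="activation"),
        Parameter("Vd", *sb["Vd"], 1.0, kind="activation"),
        Parameter("Ve", *sb["Ve"], 1.0, kind="activation"),
    ]
    for i in range(candidate_roots.n_root):
        params.append(Parameter(f"root_{i}", 0, 1, 1, kind="activation"))
    space = ParameterSpace(params)
    target_trim = _qrs_trim(target_qrs, qrs_window)
    apd_uniform = np.full(mesh.n_nodes, int(uniform_apd))
    duration = qrs_window[1]

    def forward(p):
        bits = [p[f"root_{i}"] > 0.5 for i in range(candidate_roots.n_root)]
        if not any(bits):
            raise InvalidArgumentError("no active root in proposal")
        roots = RootNodes(
            candidate_roots.indices[np.array(bits)],
            candidate_roots.offsets[np.array(bits)],
        )
        speeds = ConductionSpeeds(Vf=vf, Vs=p["Vs"], Vn=vn, Vd=p["Vd"], Ve=p["Ve"], Vp=vp)
        act = solve_activation(mesh, speeds, roots)
        vm = assemble_vm(
            mesh, act, apd_uniform, table, duration + 1.0, 1.0,
            check_coverage=False,
        )
        sim = pseudo_ecg(vm, mesh, electrodes, rr=target_qrs.rr)
        sim = normalise_r_progression(sim, target_qrs, qrs_window)
        return _qrs_trim(sim, qrs_window)

    pop = smc_abc(forward, target_trim, space, cfg)
    best, _ = pop.best
    bits = np.array(
        [best[f"root_{i}"] > 0.5 for i in range(candidate_roots.n_root)]
    )
    if not bits.any():
        bits[:] = True
    speeds = ConductionSpeeds(
        Vf=vf, Vs=best["Vs"], Vn=vn, Vd=best["Vd"], Ve=best["Ve"], Vp=vp
    )
    roots = RootNodes(candidate_roots.indices[bits], candidate_roots.offsets[bits])
    return speeds, roots, pop


def infer_repolarisation(
    mesh,
    activation,
    speeds,
    target: ECGRecording,
    space: ParameterSpace,
    cfg: SMCConfig,
    table,
    electrodes,
    smoothing=None,
    duration=500.0,
    qrs_window=(0.0, 120.0),
) -> ParticlePopulation:
    """SMC-ABC over the APD-field parameters with the fixed activation map."""
    from .ecg import normalise_r_progression, pseudo_ecg
    from .re_model import APDFieldParams, run_pseudo_diffusion_re

    def forward(p):
        apd_params = APDFieldParams(
            g_ab=p["g_ab"], g_tm=p["g_tm"], g_pa=p["g_pa"], g_tv=p["g_tv"],
            apd_min=p["apd_min"], apd_max=p["apd_max"],
        )
        vm = run_pseudo_diffusion_re(
            mesh, activation, apd_params, table, speeds, smoothing, duration
        )
        sim = pseudo_ecg(vm, mesh, electrodes, rr=target.rr)
        return normalise_r_progression(sim, target, qrs_window)

    return smc_abc(forward, target, space, cfg, keep_ecgs=True)


# ---------------------------------------------------------------------------
# Sobol sensitivity
# ---------------------------------------------------------------------------


def sobol_sensitivity(forward, ranges, n_base=1024, seed=0):
    """Saltelli-design Sobol indices of ``forward`` outputs.

    ``forward`` maps a parameter dict to a dict of scalar outputs (or a
    single scalar); ``ranges`` is an ordered ``{name: (lo, hi)}`` mapping.
    ``n_base`` must be a power of two. Returns a DataFrame with columns
    (output, parameter, S1, ST) plus the failed-evaluation count as attrs.
    """
    names = list(ranges)
    d = len(names)
    if n_base < 2 or (n_base & (n_base - 1)) != 0:
        raise InvalidArgumentError("n_base must be a power of 2")
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    base = sampler.random(n_base)
    A01, B01 = base[:, :d], base[:, d:]

    def scale(u):
        out = np.empty_like(u)
        for j, nm in enumerate(names):
            lo, hi = ranges[nm]
            out[:, j] = lo + u[:, j] * (hi - lo)
        return out

    A, B = scale(A01), scale(B01)

    def run(mat):
        rows = []
        ok = []
        for r in mat:
            try:
                out = forward(dict(zip(names, r)))
            except Exception:
                logger.warning("forward model failed in Sobol design", exc_info=False)
                rows.append(None)
                ok.append(False)
                continue
            if np.isscalar(out):
                out = {"output": float(out)}
            rows.append({k: float(v) for k, v in out.items()})
            ok.append(True)
        return rows, np.array(ok)

    fa, ok_a = run(A)
    fb, ok_b = run(B)
    fab = []
    ok_ab = np.ones((d, n_base), dtype=bool)
    for j in range(d):
        ab = A.copy()
        ab[:, j] = B[:, j]
        r, ok = run(ab)
        fab.append(r)
        ok_ab[j] = ok
    valid = ok_a & ok_b & ok_ab.all(axis=0)
    n_failed = int(n_base - valid.sum())
    if valid.sum() < 8:
        raise InvalidArgumentError("too many forward failures in Sobol design")
    outputs = list(fa[int(np.nonzero(valid)[0][0])].keys())
    records = []
    for out_name in outputs:
        ya = np.array([fa[i][out_name] for i in range(n_base) if valid[i]])
        yb = np.array([fb[i][out_name] for i in range(n_base) if valid[i]])
        # centre the outputs: the first-order estimator is a product form and
        # degrades catastrophically when |mean| >> sd
        mu = np.mean(np.concatenate([ya, yb]))
        ya = ya - mu
        yb = yb - mu
        var = np.var(np.concatenate([ya, yb]))
        for j, nm in enumerate(names):
            yab = np.array(
                [fab[j][i][out_name] for i in range(n_base) if valid[i]]
            ) - mu
            if var <= 1e-300:
                s1 = st = 0.0
            else:
                s1 = float(np.mean(yb * (yab - ya)) / var)   # Saltelli 2010
                st = float(0.5 * np.mean((ya - yab) ** 2) / var)  # Jansen
            records.append(
                {"output": out_name, "parameter": nm, "S1": s1, "ST": st}
            )
    df = pd.DataFrame.from_records(records)
    df.attrs["n_failed"] = n_failed
    df.attrs["n_base"] = n_base
    return df
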