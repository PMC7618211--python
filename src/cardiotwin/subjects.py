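"""Ground-truth virtual subjects for end-to-end testing without clinical data.

A synthetic subject bundles an idealized geometry, a known activation
configuration (root nodes + conduction speeds), a known linear APD-gradient
field and the R-normalised 12-lead pseudo-ECG generated by running the
pseudo-diffusion reaction-Eikonal forward model on that truth. Truth values
are sampled from documented physiological ranges: conduction speeds around
the prescribed 65/48 cm/s myocardial values, APD-field parameters inside the
sensitivity-analysis ranges, and heart rate in the 48-74 bpm span of healthy
resting adults.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .cells import APLookupTable, CellModelParams, build_lookup
from .ecg import ECGRecording, pseudo_ecg
from .eikonal import ConductionSpeeds, RootNodes, solve_activation
from .errors import InvalidArgumentError
from .geometry import ElectrodeSet, Mesh, generate_idealized_biventricle, place_electrodes
from .re_model import APDFieldParams, SmoothingConfig, run_pseudo_diffusion_re

#: documented truth-sampling ranges (emulation targets, not clinical claims)
TRUTH_RANGES = {
    "Vs": (40.0, 80.0),       # cm/s
    "Vd": (100.0, 180.0),
    "Ve": (60.0, 120.0),
    "g_ab": (-1.0, 1.0),
    "g_tm": (-1.0, 1.0),
    "g_pa": (-1.0, 1.0),
    "g_tv": (-1.0, 1.0),
    "apd_min": (180.0, 230.0),  # ms
    "apd_max": (270.0, 300.0),
    "heart_rate": (48.0, 74.0),  # bpm
}


@dataclass
class SyntheticSubject:
    mesh: Mesh
    electrodes: ElectrodeSet
    speeds: ConductionSpeeds
    roots: RootNodes
    apd_params: APDFieldParams
    cycle_length: float           # ms
    target: ECGRecording          # R-normalised (max |R| = 1)
    seed: int
    table: APLookupTable | None = None

    @property
    def activation(self):
        return solve_activation(self.mesh, self.speeds, self.roots)

    def truth_dict(self):
        return {
            "speeds": {
                k: getattr(self.speeds, k)
                for k in ("Vf", "Vs", "Vn", "Vd", "Ve", "Vp")
            },
            "roots": json.loads(self.roots.to_json()),
            "apd_params": self.apd_params.as_dict(),
            "cycle_length": self.cycle_length,
            "seed": self.seed,
        }

    def save(self, directory):
        """Write the subject bundle: mesh VTK + truth JSON + target ECG CSV."""
        from .vtkio import write_vtk

        os.makedirs(directory, exist_ok=True)
        write_vtk(os.path.join(directory, "mesh.vtk"), self.mesh)
        with open(os.path.join(directory, "truth.json"), "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1)
        self.target.to_csv(os.path.join(directory, "target_ecg.csv"))
        self.electrodes.to_json(os.path.join(directory, "electrodes.json"))


def _snap(value, resolution):
    return float(np.rint(value / resolution) * resolution)


def pick_root_candidates(mesh: Mesh, rng, n_candidates=6):
    """Seeded endocardial root-node candidates (apical-leaning, both cavities)."""
    endo = np.nonzero(mesh.is_endocardial & (mesh.ab < 0.7))[0]
    if endo.size == 0:
        endo = np.nonzero(mesh.is_endocardial)[0]
    if endo.size == 0:
        raise InvalidArgumentError("mesh has no endocardial nodes")
    n = min(n_candidates, endo.size)
    idx = rng.choice(endo, size=n, replace=False)
    offsets = rng.uniform(0.0, 8.0, size=n)
    offsets[0] = 0.0  # anchor the earliest site
    return RootNodes(np.sort(idx), offsets)


def make_synthetic_subject(
    seed=0,
    geometry="biventricle",
    counts=(26, 18, 3),
    overrides=None,
    table=None,
    cell_params=None,
    n_roots=3,
    duration=500.0,
    smoothing=None,
    torso_scale=3.0,
    lookup_kwargs=None,
) -> SyntheticSubject:
    """Generate a virtual subject with known truth and target ECG.

    ``overrides`` may pin any entry of :data:`TRUTH_RANGES`; everything else
    is sampled from its documented range with the given seed. If no lookup
    ``table`` is supplied one is built for the cell model (slow; prefer to
    share a table across subjects).
    """
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    if geometry == "biventricle":
        mesh = generate_idealized_biventricle(*counts)
    elif isinstance(geometry, Mesh):
        mesh = geometry
    else:
        raise InvalidArgumentError(f"unknown geometry spec {geometry!r}")
    electrodes = place_electrodes(mesh, torso_scale)

    def draw(name):
        if name in overrides:
            return float(overrides[name])
        lo, hi = TRUTH_RANGES[name]
        return float(rng.uniform(lo, hi))

    speeds = ConductionSpeeds(
        Vf=65.0, Vs=draw("Vs"), Vn=48.0, Vd=draw("Vd"), Ve=draw("Ve"), Vp=300.0
    )
    apd_params = APDFieldParams(
        g_ab=_snap(draw("g_ab"), 0.1),
        g_tm=_snap(draw("g_tm"), 0.1),
        g_pa=_snap(draw("g_pa"), 0.1),
        g_tv=_snap(draw("g_tv"), 0.1),
        apd_min=_snap(draw("apd_min"), 2.0),
        apd_max=_snap(draw("apd_max"), 2.0),
    )
    if all(
        abs(getattr(apd_params, g)) < 0.05 for g in ("g_ab", "g_tm", "g_pa", "g_tv")
    ):
        apd_params.g_ab = 0.5  # avoid the degenerate all-zero gradient corner
    heart_rate = draw("heart_rate")
    cycle_length = round(60000.0 / heart_rate)
    if "roots" in overrides:
        roots = overrides["roots"]
    else:
        roots = pick_root_candidates(mesh, rng, n_candidates=n_roots)
    cell_params = cell_params or CellModelParams(cycle_length=max(cycle_length, 650.0))
    if table is None:
        table = build_lookup(cell_params, **(lookup_kwargs or {}))
    activation = solve_activation(mesh, speeds, roots)
    smoothing = smoothing or SmoothingConfig()
    vm = run_pseudo_diffusion_re(
        mesh, activation, apd_params, table, speeds, smoothing, duration
    )
    rr = cycle_length / 1000.0
    raw = pseudo_ecg(vm, mesh, electrodes, rr=rr)
    qrs = raw.times <= 120.0
    amp = np.abs(raw.data[:, qrs]).max()
    if amp <= 0:
        raise InvalidArgumentError("degenerate target ECG (flat QRS)")
    target = ECGRecording(raw.data / amp, rate=raw.rate, rr=rr)
    return SyntheticSubject(
        mesh=mesh,
        electrodes=electrodes,
        speeds=speeds,
        roots=roots,
        apd_params=apd_params,
        cycle_length=float(cycle_length),
        target=target,
        seed=seed,
        table=table,
    )
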