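# cardiotwin

Desk-scale cardiac digital twins of ventricular electrophysiology: a fast
**pseudo-diffusion reaction-Eikonal** (PDRE) simulator with biophysically
parameterised repolarisation, likelihood-free (**SMC-ABC**) inference of
activation and repolarisation parameters from 12-lead ECG morphology,
translation of inferred twins to **monodomain** reaction-diffusion
simulations, and virtual evaluation of hERG-channel (IKr) blocking drugs with
uncertainty propagation.

The package is aimed at researchers in computational cardiac
electrophysiology who want an inspectable, single-machine implementation of
the full twin-generation loop - from mesh to inferred "physiological
envelope" to dose-response curves - on idealized geometries that stand in for
image-derived anatomies.

## The model in brief

**Forward model.** Activation times solve the anisotropic Eikonal equation
`∇tₐᵀ V ∇tₐ = 1` with orthotropic conduction speeds `(V_f, V_s, V_n)` and
earliest-activation root nodes; it is solved as a multi-source Dijkstra
problem on the mesh edge graph. The reaction operator is precomputed: a
lookup table `K_APD : APD → (G_Ks, U_APD(t))` maps every integer APD (ms) to
the slow-delayed-rectifier conductance that produces it and to a 601-sample
action potential paced to steady state with a diffusive stimulus current
`I_diff(t) = A₁e^{-(t-μ₁)²/2σ₁²} - A₂e^{-(t-μ₂)²/2σ₂²}`. Membrane potential
is assembled as `U(x,t) = U_APD(x)(t - tₐ(x))`, and diffusion during
repolarisation is approximated by repeated application of an orthotropic
neighbour-averaging smoothing operator with per-edge weights

```
k_m = 1 / sqrt( (max(V)/V_f · p·f)² + (max(V)/V_s · p·s)² + (max(V)/V_n · p·n)² )
```

**APD field.** `APD(x)` is the min-max-normalised weighted sum
`q = g_ab·ab + g_tm·tm + g_pa·pa + g_tv·tv` of four ventricular coordinates,
mapped onto `[APD_min, APD_max]`.

**ECG and inference.** Eight independent leads (I, II, V1-V6) come from the
pseudo-ECG volume integral `φ(e) = -∫ ∇U · ∇(1/r) dV`, R-normalised by a
single cross-lead factor. The inference discrepancy is

```
ε = (1/8) Σᵢ [ w_p (1 - PCCᵢ)² + w_r RMSEᵢ / max|R_target| ],  w_p = 100, w_r = 2
```

minimised by a lattice-constrained SMC-ABC sampler (adaptive threshold,
resample-move kernel) whose final population is the twin's uncertainty
envelope.

**Drugs.** IKr block follows the Hill equation
`G_block = 1/(1 + ([D]/IC50)^h)`; QTc uses Fridericia's `QT/RR^(1/3)`.

## Worked example

Generate a synthetic ground-truth subject, infer its repolarisation
parameters with the subject's true activation fixed, and inspect the match:

```python
import numpy as np
from cardiotwin import (CellModelParams, build_lookup, make_synthetic_subject,
                        SMCConfig)
from cardiotwin.inference import infer_repolarisation, repolarisation_space
from cardiotwin.ecg import ECGRecording, lead_pcc, lead_rmse

table = build_lookup(CellModelParams(), apd_bounds=(178, 302), n_beats=100)
subject = make_synthetic_subject(seed=11, counts=(26, 18, 3), table=table)
cfg = SMCConfig(population=32, cutoff=0.5, seed=101)
pop = infer_repolarisation(subject.mesh, subject.activation, subject.speeds,
                           subject.target, repolarisation_space(), cfg,
                           table, subject.electrodes)
pccs = [np.mean(lead_pcc(ECGRecording(e), subject.target)) for e in pop.ecgs]
print(f"iterations: {len(pop.history)}, terminated by: {pop.terminated_by}")
print(f"median lead PCC: {np.median(pccs):.3f}")
print(f"best parameters: {pop.best[0]}")
```

On one CPU this prints (about a minute of sampling):

```
iterations: 4, terminated by: cutoff
median lead PCC: 0.987
best parameters: {'g_ab': -0.7, 'g_tm': -0.4, 'g_pa': 0.9, 'g_tv': -0.9,
                  'apd_min': 198.0, 'apd_max': 272.0}
```

The inferred population reproduces the target ECG's T-wave morphology
(median lead-wise Pearson correlation 0.987 against a 0.9 threshold for a
clinically equivalent match), and the best particle sits near the hidden
truth (`g_pa = 0.9`, `g_tv = -0.9` exact; APD bounds within the
identifiability limits of an ECG-only inverse problem).

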