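# Methods

This note records the modelling and numerical choices behind `cardiotwin`,
what the synthetic fixtures do and do not emulate, and the known limitations
of a desk-scale implementation.

## Pseudo-diffusion reaction-Eikonal forward model

The monodomain equation is treated by a "full split": the reaction operator
is solved for the whole cycle first, then a smoothing operator approximating
the diffusion operator is applied to the repolarisation phase.

* **Activation** (`eikonal`). First-arrival times on the mesh edge graph by
  multi-source Dijkstra, with the orthotropic metric
  `sqrt((p·f/V_f)² + (p·s/V_s)² + (p·n/V_n)²)` on myocardial edges and
  isotropic endocardial speeds: dense region `V_d` where both endpoints are
  endocardial with apex-to-base coordinate < 0.4 (apical, Purkinje-dense),
  sparse `V_e` elsewhere on the endocardium. The edge graph contains every
  vertex pair sharing an element; for hexahedral slabs this adds face/body
  diagonals, bounding the overestimation of graph geodesics over continuous
  Eikonal distances by a few percent (26-neighbourhood) instead of the ~41%
  worst case of a 6-neighbourhood. The residual bias is absorbed by the
  inference, which calibrates speeds against this same solver. Edge frames
  are endpoint-averaged and re-orthogonalised (Gram-Schmidt) so the metric
  decomposition is exact.
* **Reaction** (`cells`, `re_model.assemble_vm`). Node potentials are
  time-shifted copies of precomputed action potentials keyed by the node's
  integer APD; fractional activation times interpolate linearly between the
  1 kHz table samples. Before activation the node sits at the table's
  resting potential.
* **Pseudo-diffusion** (`re_model.smooth*`). One smoothing pass replaces
  every node value by the `k_m`-weighted average of its 1-ring plus itself
  weighted by `k_i` (default 10 mm⁻¹, i.e. a 0.1 mm self-distance); the
  per-edge weight favours edges aligned with the fastest conduction
  direction and is bounded by `min(V)/max(V)/|p| ≤ k_m ≤ 1/|p|`. Output
  frames between 100 and 450 ms (approximate end of activation to end of
  repolarisation) receive `n_B = floor((t-100)/Δt_B)+1` cumulative passes
  (`Δt_B` = 20 ms); each frame is smoothed independently of the others,
  which reads the operator-splitting form `(e^{BΔt_B})^{n_B} Û` literally.
  The denominator of the weighted average is `Σk_m + k_i` for both terms (a
  convex combination), the only normalisation-preserving reading.

A consequence worth knowing: by the end of the window a frame has received
~18 passes, which essentially homogenises whatever spatial gradient remains.
Smoothing therefore always reshapes the T wave by an amount comparable to
the T amplitude whenever repolarisation is spatially staggered; the
"diffusion is near-null" intuition only holds in the limit of spatially
uniform repolarisation, and the test suite asserts exactly that limit
property (20x more uniform activation shrinks the smoothing-induced T-wave
change by >10x).

## Cell model and lookup table

The bundled ionic model is a human-ventricular-class surrogate derived from
the Beeler-Reuter formulation (8 states + the split gate), chosen because a
full modern human ventricular model is out of scope while every mechanism
the pipeline exercises must be present. Two modifications matter:

* the delayed-rectifier current is split into an explicit **rapid** (IKr,
  gate rates x2.5, weight 0.5) and **slow** (IKs, gate rates x0.4, weight
  0.5) component, each with its own conductance scaler, giving a monotone
  one-to-one APD-G_Ks map over gKs folds 1/50..50 and a genuine IKr-block
  (dofetilide) target;
* the sodium activation gate is shifted by +10 mV so the biphasic diffusive
  stimulus current (net charge ≈ -4 mV of depolarisation; the positive lobe
  reaches ≈ -58 mV) can trigger the upstroke, as it does for
  biophysically detailed human models with lower thresholds.

The "widened-APD-range" baseline modifications (gKs x5, gKr x0.5, faster
L-type activation: `tau_jca` 75 → 60 ms maps to a 75/60 scaling of the
slow-inward activation-gate rates) are on by default; they widen the gKs
controllable APD span relative to the unmodified baseline.

Integration is fixed-step Rush-Larsen for gates with forward-Euler voltage
and calcium at `dt` = 0.02 ms. Gate steady states and update factors, IK1
and the delayed-rectifier driving function are pre-tabulated on a 0.05 mV
grid, so the identical tables (and hence identical cell dynamics) serve
single-cell pacing and the tissue-scale monodomain reaction sub-step. An
adaptive stiff integrator was deliberately not used: bit-consistency between
the lookup-table action potentials and the tissue reaction operator is worth
more here than adaptive error control, and Rush-Larsen at 0.02 ms resolves
this model's stiffest gate (τ_m ≈ 0.04 ms near threshold at the table's
resolution) within the APD reproducibility the table requires (±0.5 ms).

The table itself (`build_lookup`) paces a population uniformly sampled in
gKs (default 64 cells over 1/50..50-fold), then refines by per-key secant
search on the monotone APD-gKs map until every integer APD key in the
requested bounds has a steady-state waveform within 0.5 ms of its key.
Waveforms are stored for 600 ms at 1 kHz starting at the upstroke (601
samples). Default pacing is 100 beats at the subject's cycle length; tests
use 12-30 beats, which changes APDs by well under the table's 1 ms key
tolerance contract for this model. For drug evaluation the table is
*re-paced, not rebuilt*: the inferred spatial gKs field stays fixed and each
entry's waveform is re-simulated with the Hill-blocked gKr, so the stored
APDs exceed their nominal keys by exactly the drug effect.

## Geometry fixtures

* **Slab**: regular hexahedral grid, fibres rotated about z; coordinates are
  normalised axis positions (`ab`←x, `tv`,`pa`←y, `tm`←z).
* **Biventricle**: an implicit two-cavity solid (outer epicardial ellipsoid,
  LV and RV cavity ellipsoids, truncated at a base plane) sampled on a
  lattice, surface nodes snapped onto their analytic surface, connected by
  Delaunay tetrahedra (largest connected component kept, slivers dropped).
  Coordinates are analytic: `tm` from the endo/epi implicit distances (0 on
  either endocardium, 1 on the epicardium), `ab` from normalised height,
  `tv`/`pa` from normalised x/y, `rt` from azimuth with a posterior seam.
  Fibres follow a rule-based helix, +60° (endo) to -60° (epi) linear in
  `tm`, built on the analytic transmural gradient with a radial fallback
  where that gradient vanishes (septal mid-wall ridge, sub-apical region).
  Default counts (26, 18, 3) give ≈ 4.3k nodes / 23k tets.
* **Electrodes**: nine points on the bounding ellipsoid scaled by a torso
  factor (default 3), at fixed documented azimuth/height fractions; azimuths
  are measured from the mesh's own anterior (`pa`) towards its right (`tv`)
  direction, so mirrored meshes produce mirrored electrodes. Limb leads and
  the Wilson central terminal give the 8 independent leads.

## ECG, biomarkers, discrepancy

The pseudo-ECG uses the infinite-homogeneous-conductor dipole integral with
unit diffusivity; per-element constant gradients (linear tetrahedra;
face-mean differences on axis-aligned hexahedra) are precomputed into one
weight vector per electrode, so a full 8-lead ECG is a single matrix
product. Simulated recordings are scaled by one cross-lead factor matching
the reference R amplitude inside the QRS window (default 0-120 ms),
preserving the R-progression.

T-wave biomarkers: the T peak is the largest-absolute-amplitude extremum
after the QRS end (default 100 ms); the T end uses the maximum-slope tangent
anchored on the *last* descending limb of the complex (last excursion above
30% of the peak), which measures multi-lobed desk-scale T waves to the end
of their final lobe; a threshold alternative (last excursion above 5% of the
T peak) sits behind a flag. QT is lead-averaged; QTc uses Fridericia.

The discrepancy is the morphology-weighted form with `w_p` = 100, `w_r` = 2;
zero-variance leads score PCC 0 with a warning.

## Inference

SMC-ABC operates on discretised lattices (2 ms for APD bounds, 0.1 for
gradient weights) with hyperparameters population 120, sampling rate 50%,
cut-off 0.5, uniqueness threshold 50% as defaults (tests and the acceptance
experiment use population 32, a scaled-down but otherwise identical
configuration). "Sampling rate" is read as the fraction of the population
replaced per iteration: each iteration drops that worst fraction, sets the
threshold to the surviving maximum, and refills slots by Metropolis
resample-move (3 lattice random-walk moves per slot, widths adapted to the
survivors' spread, acceptance iff ε ≤ threshold). Termination: threshold ≤
cut-off, uniqueness below threshold, or the iteration cap. Forward failures
receive infinite discrepancy and a log entry, never silent removal. The
activation stage fixes `V_f`/`V_n`/`V_p` at 65/48/300 cm/s, infers
(`V_s`, `V_d`, `V_e`) plus root-inclusion bits against the QRS window only
(uniform-APD assembly), and passes its best match to the repolarisation
stage; a joint mode is possible by concatenating the spaces but the
sequential workflow is the default.

Sobol sensitivity uses a Saltelli design on a scrambled Sobol sequence with
the Saltelli-2010 first-order and Jansen total-order estimators on centred
outputs. The pipeline sensitivity fixture uses a biventricle whose every
endocardial node is an earliest-activation site ("Purkinje-dense" limit), so
T-wave biomarkers respond to the APD field rather than root placement.

## Monodomain reference and translation

Structured-grid finite differences, Godunov splitting (Rush-Larsen reaction
then explicit 7-point anisotropic diffusion), axes aligned with (f, s, n).
Zero-flux boundaries use the finite-volume ghost-equals-self form, which is
discretely conservative. Defaults: `dt` 0.02 ms, χ = 1400 cm⁻¹,
C_m = 1 µF/cm². The stability bound `dt ≤ h²/(2ΣD)` is checked before
starting. Activation times are recorded in-kernel by interpolated threshold
crossing at -20 mV.

Conductivity calibration bisects σ in an 80 mm cable (probes at 40% and 60%
of its length, 16 mm apart, inside the middle third) until the measured CV
is within 0.3% of target, then re-measures independently. Cable defaults
`h` = 0.125 mm, `dt` = 0.01 ms: at these values halving the step changes CV
by < 2% (0.25 mm was ~5% from the converged value). Translation to a finer
grid maps gKs scalers by closest-point (lowest index on ties), calibrates
each σ at the *target grid's own spacing* - the same convention CV-tuning
toolkits use - and stimulates 1 mm balls around the coarse root nodes with
their activation-time offsets.

Diffusive-current extraction aligns each node's stored diffusion term at
its activation time, placed 14 ms into the window to mirror the stimulus
convention, takes the pointwise median and fits the two-Gaussian form by
bounded least squares.

## Synthetic subjects: what they emulate, and not

A subject samples conduction speeds around the prescribed myocardial values,
APD-field parameters on the inference lattice within the sensitivity ranges,
heart rate in 48-74 bpm, and 3 apical-leaning endocardial root nodes with
0-8 ms offsets; the target ECG is the subject's own PDRE pseudo-ECG,
R-normalised to max |R| = 1. Twin-recovery experiments on such subjects test
the inference machinery under a *well-specified* forward model: no
measurement noise, no electrode-position error, no anatomical mismatch, no
beat-to-beat variability. Passing them shows the sampler and forward model
are correct and identifiable at this scale - not that clinical ECGs would be
matched equally well.

## Problem sizes

Chosen as the package's standard desk-scale configuration: biventricles of
~0.8-4.3k nodes; slab translation on 20x20x5 mm (coarse 1 mm for PDRE, fine
0.5 mm for monodomain); SMC population 32 for experiments and tests
(default 120 retained for real use); Saltelli bases 32 (pipeline) and 1024
(analytic estimator checks); lookup tables of 61-131 keys.

## Known limitations

* The surrogate cell model reproduces class-level behaviour (APD control by
  gKs, IKr-block prolongation, conduction) but not the detailed ionic
  repertoire of modern human models; its steep phase 3 plus coarse meshes
  yields lobed T waves more often than in fine-mesh studies.
* The QT interval's global-sensitivity ranking is resolution-sensitive at
  desk scale: with only ~20 ms of transmural activation delay against a
  30 ms APD_max range and lobed T-end detection, the largest first-order
  index moves between APD_max, APD_min and the transmural/apex-base
  gradients across seeds and mesh sizes rather than being APD_max
  decisively.
* Monodomain supports structured grids only (cable/slab scope); whole-organ
  monodomain and Purkinje-tree synthesis are out of scope.
* The biventricular fixture's coordinates are analytic conveniences, not a
  full universal-coordinates implementation; `rt` is generated but unused by
  the APD field.
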