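# hemoforce

Hemodynamic force (HDF) analysis of 4D-flow cardiac magnetic resonance:
from corrupted phase-contrast velocity fields to biventricular force
traces, per-phase force metrics, ventricular volumetrics and cohort
statistics — with analytic flow phantoms standing in for patient data.

## Who this is for

4D-flow CMR measures the three-directional blood velocity field throughout
the heart over the cardiac cycle. From it one can compute the
*hemodynamic force*: the net force the moving blood exchanges with the
myocardium, an emerging imaging biomarker of ventricular function used to
study loading conditions such as left-to-right shunts (e.g. atrial septal
defects) and their correction. This package implements that analysis as a
tested, reusable Python library for imaging researchers, plus a thin
`hemoforce` command-line wrapper for pipeline runs.

## The method

The intraventricular pressure gradient is evaluated from the Navier-Stokes
momentum balance, per voxel and per time frame:

```
∇p = −ρ (∂v/∂t + (v·∇)v) + μ ∇²v
```

with ρ the blood density (default 1060 kg/m³), μ its dynamic viscosity
(default 4.0·10⁻³ Pa·s), ∂v/∂t by cyclic central differences over the
retrospectively gated (periodic) cycle, and spatial derivatives by central
differences on the voxel grid. Absolute pressure never enters; only the
time-varying gradients that drive filling and ejection are used.

Integrating over the time-varying ventricular blood pool V(t) gives the
global force vector in Newton:

```
F(t) = ∫_V(t) ∇p dV
```

F(t) is decomposed onto a right-handed anatomical triad built from the
atrioventricular (AV) valve-plane normal (apical-basal axis) and the left
ventricular outflow tract direction, Gram-Schmidt-orthogonalized
(lateral-septal axis); the third axis (inferior-anterior) completes the
triad. The right ventricle uses the same directions with RV labels
(septum-free wall, diaphragm-RVOT). Traces are resampled to a reference
cardiac cycle with end systole anchored at 40% of the R-R interval, and
summarized as RMS and peak per direction in systole `[0, 0.4)` and
diastole `[0.4, 1)`.

Before force computation, two phase-contrast artifacts are repaired:
VENC aliasing by temporal unwrapping (inter-frame jumps beyond the
encoding limit are restored by multiples of 2·VENC), and residual
background phase offsets by fitting a low-order 3D polynomial to
stationary-tissue voxels and subtracting it.

Volumetrics (EDV, ESV, SV, EF, BSA-indexed values via Mosteller's formula,
cardiac index, planimetric Qp/Qs) and a distribution-gated statistics
workflow (Shapiro-Wilk gate → t-tests / Wilcoxon / Mann-Whitney /
chi-square / Pearson / Spearman, median [IQR] summaries) round out the
pipeline.

## Worked example

```bash
python examples/phantom_force_trace.py
```

```
blood-pool volume      : 101.6 mL
computed peak force    : 0.3349 N
closed-form peak force : 0.3349 N
relative error         : 1.11e-13
apex-base systolic RMS : 0.2134 N
apex-base diastolic RMS: 0.2494 N
```

The phantom is a spatially uniform velocity oscillation (amplitude
0.5 m/s, 1 s cycle, 25 frames) inside a ~100 mL blood pool at clinical
resolution (2.2×2.2×2.5 mm, VENC 150 cm/s). For such a field the
convective and viscous terms vanish and the force reduces to
−ρ V dv/dt along the apex-base axis; the pipeline reproduces the
closed form to round-off. The RMS values are the per-phase force metrics a
clinical study would tabulate (in Newton).

Other examples: `preprocessing_round_trip.py` (offset + aliasing injection
and exact recovery), `volumetry_and_indices.py` (volume curve, EF, BSA
indexing), `cohort_statistics.py` (simulated pre/post cohort and the gated
comparison report). A full phantom-to-report run:

```bash
hemoforce run-all --config examples/config.yaml
```

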