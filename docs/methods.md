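# Methods

## Model

Hemodynamic force analysis treats the ventricular blood pool as an
incompressible Newtonian fluid. The pressure-gradient field is evaluated
directly from the measured velocity via the Navier-Stokes momentum
balance,

∇p = −ρ (∂v/∂t + (v·∇)v) + μ ∇²v,

and the global hemodynamic force is its volume integral over the
time-varying blood pool, F(t) = ∫ ∇p dV, reported in Newton with the sign
convention F = +∫∇p dV. Three physical contributions enter: temporal
acceleration (dominant under physiological flow), convective acceleration,
and viscous friction. Absolute pressure is deliberately absent — the
method quantifies only the dynamic gradients that drive filling and
ejection, which is what makes it applicable to volume-overload conditions
where absolute pressures are near normal.

Assumptions: the cycle is periodic (retrospective gating), blood density
and viscosity are spatially constant, and the velocity field is defined on
the full acquired volume so spatial stencils at the mask boundary may use
voxels outside the blood pool (no erosion is applied for gradient
evaluation; the analytic phantom oracles are instead evaluated on eroded
interiors where their profiles are discontinuous at walls).

## Discretization

* Temporal derivative: cyclic central difference, (v[k+1] − v[k−1]) / 2Δt
  with wrap-around indexing. On a sampled sinusoid this attenuates the
  amplitude by sin(ω Δt)/(ω Δt); the phantom oracles include this factor,
  so pipeline-vs-oracle comparisons isolate genuine defects rather than
  known sampling effects. At 25 frames per cycle the factor is 0.9896.
* Spatial first derivatives: central differences (one-sided at the grid
  boundary), via `numpy.gradient`.
* Laplacian: hand-written three-point second differences per axis, with the
  shifted stencil (f₀ − 2f₁ + f₂)/h² at boundaries, so the operator is
  exact on quadratic profiles everywhere — the property that makes the
  parabolic pipe-flow phantom an exact oracle.
* Volume integral: voxel-count sum times voxel volume, following the
  time-varying mask; an empty mask frame contributes zero force and a
  warning.

## Axes, resampling, metrics

The decomposition triad is e₁ = normalized AV-plane normal (apex → base
positive — the sign convention is fixed here so traces are comparable
across subjects), e₂ = LVOT direction orthogonalized against e₁
(Gram-Schmidt), e₃ = e₁ × e₂. Right-ventricular analysis uses the same
vectors, relabeled (septum-free wall, diaphragm-RVOT).

Force traces are mapped to a reference cycle by a piecewise-linear time
warp sending [0, t_ES] → [0, 0.40] and [t_ES, RR] → [0.40, 1], then
linearly interpolated at n_ref uniform fractions (default n_ref = 100, a
multiple of 1/0.40 so the systole/diastole boundary falls exactly on a
sample). End systole is taken from the volume-curve minimum (or the
annotation), not from gated frame metadata, so phantoms and patient data
are treated identically. RMS and peak per direction are computed after
resampling, on the reference cycle, with systole = [0, 0.40) and diastole
= [0.40, 1).

## Preprocessing

Aliasing: velocities beyond ±VENC wrap by 2·VENC. Unwrapping is temporal:
per voxel, successive frame differences with magnitude > VENC are
implausible for periodic flow sampled at clinical frame rates and are
corrected by the restoring multiple of 2·VENC (`numpy.unwrap` with period
2·VENC). This is a deliberate simplification of production spatiotemporal
region-growing unwrappers; it is exact whenever |v| < 2·VENC and true
inter-frame changes stay below VENC, which the phantom generator's wrap
regime guarantees. A wrap that is already present in the first frame, or a
super-VENC jump in the true signal, is outside its contract.

Background offsets: eddy currents leave a spatially smooth, temporally
constant velocity offset. Voxels whose temporal standard deviation is
below a threshold in all three components are declared stationary tissue
(default 0.02 m/s — safely above numerical noise on nearly noise-free
data, far below the ~0.35 m/s temporal SD of pulsatile blood voxels; on
noisy data the threshold must sit above the noise floor, e.g. twice the
noise SD, and is exposed as a parameter). A 3D polynomial of total degree
≤ `poly_order` (default 2 — captures the linear-plus-mildly-curved
profiles typical of scanner offsets without overfitting sparse static
regions; orders 1–3 supported) is least-squares fitted to the
time-averaged velocity over static voxels, per component, on voxel
coordinates normalized to [−1, 1], and subtracted from every frame.
Order of operations is unwrap first, then offset correction: offsets are
small relative to VENC, while wraps are VENC-scale and would wreck the
polynomial fit.

## Synthetic data

No patient data ships with the package; the generator emulates the
acquisition scale of a pediatric whole-heart protocol (32³ grid at
2.2×2.2×2.5 mm, 25 reconstructed phases, VENC 150 cm/s, 1 s cycle) and
provides four phantoms:

* **uniform_oscillation** — spatially uniform v(t) = A sin(2πt/T) ẑ
  (A = 0.5 m/s) inside a flow region; closed-form force with the discrete
  temporal-derivative factor. The region is surrounded by a zero-velocity
  shell that plays the role of stationary tissue, and the integration mask
  keeps a 3-voxel margin from the velocity discontinuity so every stencil
  the oracle touches sees a uniform field.
* **poiseuille** — steady parabolic pipe flow (v_max = 1 m/s, R = 1 cm);
  on the eroded interior the gradient is exactly −4μv_max/R² ẑ.
* **solid_rotation** — rigid rotation (10 rad/s); the centripetal gradient
  field is radially symmetric, so the net force over the centered mask
  cancels while ∫|∇p| dV stays finite.
* **contracting_blob** — oscillatory velocity inside an ellipsoid whose
  semi-axes vary sinusoidally (volume minimum at 40% of the cycle);
  exercises time-varying-mask integration, with an independent brute-force
  voxel sum as its oracle.

Corruption injection adds a polynomial offset (same monomial basis the
correction fits), optional rewrapping into [−VENC, VENC), and Gaussian
noise. "SNR 20 dB" in tests means noise SD one tenth of the velocity
amplitude (0.05 m/s against 0.5 m/s).

What the phantoms do **not** emulate: chamber-realistic geometry and flow
patterns, partial-volume and segmentation error, spatially varying noise,
k-space/eddy-current physics, or heart-rate variability. Passing phantom
tests therefore demonstrates numerical correctness of the operators and
the corruption-repair contracts, not clinical accuracy on patient data.

The cohort simulator draws volumetrics and twelve force metrics
(2 ventricles × 3 directions × 2 phases, RMS) lognormally around
group-typical centers taken from published pediatric shunt-cohort medians
(e.g. RV EDVi 88 mL/m² controls, 129 preop, 90 postop), with a shared
per-subject latent volume score driving both volumetrics and forces so the
volume–force correlation is tunable (`coupling`, default 0.8, is the
target log-scale correlation). Patients get paired baseline/follow-up rows
(follow-up latent scores track baseline with persistence 0.7; the
baseline→follow-up center shift is scaled by `paired_shift`, 0 for null
simulations), and a configurable number of follow-ups is missing
(default 5 of 21, leaving 16 paired records). Coefficients of variation
(0.18 volumes, 0.35 forces) were chosen once to produce overlap and
significance patterns of the same order as the published tables.

## Statistics

Each variable is gated by Shapiro-Wilk at p ≥ 0.05: normal → t-tests and
Pearson; else, if strictly positive and normal after log transform →
the same tests on the log scale; else → Wilcoxon signed-rank /
Mann-Whitney U and Spearman. The gate order (normal → lognormal →
nonnormal) is fixed here; a constant sample is classed nonnormal since
Shapiro-Wilk is undefined for it. The signed-rank null is enumerated
exactly for n ≤ 12 nonzero differences and normally approximated above —
small-cohort fidelity is the point. Chi-square is computed without
continuity correction. No multiple-testing correction is applied
(exploratory workflow); significance is p < 0.05 throughout. Summaries are
median [IQR] with linear-interpolation percentiles.

## Numerical choices and degenerate inputs

* Internal units are strict SI (m, s, m/s, N); metadata fields carry their
  unit in the name (`spacing_mm`, `venc_cm_s`) and all conversions happen
  at the I/O boundary. NIfTI headers store affines in float32, so the JSON
  sidecar carries the grid geometry at full precision and takes precedence
  on read.
* Mask resampling: trilinear interpolation of the 0/1 field thresholded at
  0.5; temporal mapping by nearest normalized cycle fraction,
  frame k ← round(n_cine·k/n_flow) mod n_cine.
* Degenerate statistics inputs (zero-variance vectors, all-zero paired
  differences, zero chi-square marginals) raise a dedicated error rather
  than returning a p-value.
* Fluid constants default to ρ = 1060 kg/m³, μ = 4.0·10⁻³ Pa·s (standard
  whole-blood values), configurable everywhere.
* The reference-cycle anchor 0.40 is a fixed convention; configurations
  overriding it are accepted with a warning.
* Problem sizes in the test suite: phantoms run at the full default
  32³ × 25 scale (with 16³ and 64³ variants for the grid-refinement
  check); statistical simulations use 300–2000 replicates, sizes at which
  binomial sampling error is well inside the asserted bands.

## Known limitations

Temporal-only unwrapping (see above); no eddy-current modeling from
gradient waveforms or Maxwell-term correction; no Poisson-based absolute
pressure reconstruction (out of scope by design); volumetrics are pure
voxel counts with no sub-voxel surface correction; the CLI handles one
ventricle per invocation (run twice for biventricular output).
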