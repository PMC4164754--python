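# Methods

`elastrec` reconstructs a relative Young's modulus map from quasi-static
ultrasound elastography data: a pair of radiofrequency (RF) echo frames
acquired before and after a small axial compression. The package contains
both the reconstruction pipeline and a synthetic study generator that
exercises it under controlled conditions.

## Model and assumptions

The tissue is modeled as linearly elastic, isotropic, nearly
incompressible (Poisson ratio ν = 0.495) and in plane strain: the
out-of-plane strain is zero, which is a reasonable approximation for
breast-like tissue under a hand-held transducer. Because no boundary
stress is measured, only the modulus *contrast* is identifiable: all
reconstructed moduli are relative to the boundary-ring value (see below),
not absolute kPa.

The pipeline has four stages.

### 1. Speckle tracking (`tracking`)

Displacements are estimated from the raw RF frames by two-step block
matching. A coarse pass estimates the bulk axial motion v = c + m·y by
integer normalized cross-correlation (NCC) on a sparse grid and a line
fit; the post frame is then companded (axially resampled) to remove it,
which suppresses the strain-induced intra-window decorrelation bias. A
fine pass tracks the residual motion with NCC block matching (default
window 2.2 × 1.8 mm, 75 % overlap) and parabolic sub-sample refinement in
both axes. Axial estimates are sub-sample accurate thanks to the RF
phase; lateral estimates are roughly an order of magnitude noisier (no
phase, coarser pitch) — the property the motion model below exists to
repair. Points whose correlation peak falls below a threshold (default
0.25) are masked.

This tracker is a deliberately simple, pluggable stand-in for more
elaborate optical-flow estimators; the downstream stages only require
"accurate axial, noisy lateral" input.

### 2. Bicubic B-spline motion model (`bspline`)

Both displacement components are tensor-product uniform cubic B-splines
(free-form deformation) on a regular knot grid, default spacings 4.75 mm
(lateral) × 4.82 mm (axial). The axial control parameters are fitted to
the tracked axial displacements by plain least squares. The lateral
parameters are *derived* from plane-strain incompressibility,
ε_xx = −ε_yy, rather than fitted to the noisy tracked lateral data: the
required lateral strain −ε_yy (an analytic spline derivative) is
integrated along x (cumulative trapezoid on a dense grid) into a lateral
displacement field, gauged to zero mean per grid row, and the lateral
control grid is fitted to it by least squares.

Two choices here deserve comment:

* **Integral vs derivative formulation.** Minimizing the dilatation
  residual Σ(∂U/∂x + ∂V/∂y)² directly over the control grid (available as
  `derive_lateral(..., method="derivative")`) produces least-squares
  ringing of the lateral strain near sharp stiffness interfaces.
  Downstream, the near-incompressible inversion operator multiplies any
  dilatation error by λ/μ ≈ 100, and we measured that this ringing alone
  collapses the reconstruction. The integral form low-passes the ringing
  and is therefore the default.
* **Gauge.** The incompressibility constraint determines U only up to an
  additive function of depth. The per-row zero-mean gauge is arbitrary;
  the inversion is insensitive to it (verified: a smooth per-row offset
  of the scale of the gauge freedom, ~5 µm, changes the mean modulus by
  < 1 %).

### 3. Direct FEM inversion (`inversion`)

The region of interest (ROI) is meshed with uniform 0.48 × 0.48 mm
bilinear quadrilaterals. A one-element ring around the ROI is assigned
unit Young's modulus — the *modulus boundary condition* that replaces
unmeasurable force or displacement boundary data. The ring stiffness
applied to the (model-evaluated) ring-node displacements gives the nodal
forces exchanged with the ROI; Newton's third law and interior
equilibrium then furnish the right-hand side f. Because each element
stiffness is linear in its modulus, K(E)·d = D·E for a sensitivity
matrix D assembled column-by-column from unit-modulus element forces, and
the per-element moduli solve the *unregularized* least-squares problem
min‖D·E − f‖₂. N_node > N_element for quadrilateral meshes, so the
system is overdetermined. Solutions are reported as-is; non-positive
values are warned about, never clamped.

**Element technology.** All operators use the mean-dilatation (B-bar)
bilinear quadrilateral with 2 × 2 Gauss integration of the deviatoric
part: at ν = 0.495 the fully integrated element locks volumetrically, and
— more importantly for an inverse problem — it couples the huge
volumetric stiffness to the pointwise dilatation of the *data*.

**Near-incompressibility is the central numerical difficulty.** At
ν = 0.495 the volumetric modulus λ exceeds the shear modulus μ by ~100×,
so the equilibrium equations weigh the dilatation content of the
displacement data ~100× more heavily than the shear content that actually
encodes the stiffness contrast. No realistic displacement estimate — and
not even pointwise samples of a 4×-finer converged forward solution —
carries the tissue's tiny true dilatation (~10⁻⁴ strain) to the required
fidelity; feeding such data to the raw least squares makes the residual
at the *true* modulus several times larger than the force scale, and the
solution collapses toward zero (an errors-in-variables shrinkage). Two
parameter-free steps make the problem well posed without any
regularization term:

1. **Exact discrete incompressibility of the data.** Before assembly, the
   lateral nodal values receive a minimum-norm correction so that every
   element preserves area exactly (element-mean dilatation = 0, solved
   through the constraint normal equations). This is the discrete form of
   the motion model's own constraint; it makes the λ-channel of the B-bar
   operator vanish identically on the data, so the 100×-amplified noise
   never enters. The correction is ~10⁻³ mm.
2. **Pressure elimination.** With the dilatation annihilated, the
   hydrostatic pressure an incompressible medium sustains is invisible to
   the data, but its force pattern still sits in the equilibrium
   equations. The least squares is therefore solved orthogonally to the
   force modes of a smooth pressure field, discretized as bilinear
   pressure on the 2×-coarser element grid — the classic inf-sup-stable
   pairing with bilinear displacements (element-wise pressure would admit
   checkerboard modes and destabilize the solve; we verified both failure
   modes). The projection is a fixed subspace elimination, not a tunable
   penalty.

Both steps are linear, so the full chain remains homogeneous of degree
one in the displacements: scaling the applied compression leaves the
modulus image exactly unchanged. When the data is an exact solution of
the same discrete operator (coincident forward/inverse meshes) the
residual at the true modulus is zero, both projections preserve it, and
recovery is exact to solver precision (< 10⁻⁶, verified).

The incompressibility correction can be disabled
(`reconstruct(..., incompressible_data=False)`) for data that already
carries a mesh-consistent volumetric component — e.g. same-mesh synthetic
solutions, or noise-free theoretical fields in scenes with strongly
depth-varying stress, where the tiny dilatations encode the pressure
decay and discarding them biases the modulus (see the target-hardening
demonstration below).

### 4. Metrics and study orchestration (`metrics`, `study`)

Accuracy is quantified on the relative scale (truth divided by the
background modulus, reconstruction already relative to the unit ring) by
the signed mean relative error, 100·mean((Ê−E)/E), and the RMSE,
100·sqrt(mean(((Ê−E)/E)²)), over all ROI elements. Region statistics
(mean ± std in rectangles and disks) support the artifact analyses.

## The synthetic study

`phantom` generates the reference scene: a 38 × 38 mm block, background
25 kPa, two 6.5 mm circular inclusions of 75 kPa (contrast 3) placed side
by side at mid depth, centers (12.35, 19.0) and (25.65, 19.0) mm — the
exact centers are the package's own layout choice. Compression is
quasi-static between perfect-slip plates: the bottom surface is fixed
axially, the top pressed down by (applied strain × height), lateral
motion free, one lateral dof pinned. Applied strains span 0.5-2.0 %. The
forward plane-strain problem is solved on a uniform mesh 4× finer than
the inversion elements (0.11875 mm); because the problem is linear, one
solve serves all strains by scaling.

RF frames are synthesized with a separable convolution point-spread
function instead of a full acoustic field simulation: 200 scatterers/mm²
(fully developed speckle) with standard-normal amplitudes are advected by
bilinear interpolation of the FEM solution; each line sums
lateral-Gaussian-beam-weighted scatterer reflectivities (beam FWHM =
λ·F# at the 19 mm focus, F# 0.5, depth-independent by default) deposited
with a windowed-sinc kernel (sub-sample delays preserve phase), convolved
with a Gaussian-enveloped 6 MHz cosine pulse whose −3 dB bandwidth is
50 %; sampling 32 MHz, 320 lines at 0.12 mm pitch, c = 1540 m/s, white
Gaussian noise at 30 dB SNR. The synthesizer reproduces speckle
statistics and tracking difficulty, not any particular scanner's
waveforms; attenuation, apodization and elevation focusing are omitted.

**Theoretical-displacement pathway.** For the no-measurement-noise
reference, the fine-mesh axial displacements are sampled on the tracker's
estimation grid and passed through the *same* motion model
(spline fit + incompressibility-derived lateral) before inversion. Raw
bilinear interpolation of both components onto the inversion mesh is
available but documented to collapse (see above); the motion model *is*
the data conditioning this inversion requires, for exact data as much as
for tracked data.

**Target-hardening demonstration.** With full-width slip compression the
stress field is depth-uniform and the artifact does not arise, so
`target_hardening_study` presses only the central 70 % of the top surface
with a smooth cos² indentation profile (a compressor narrower than the
phantom, C¹ at the contact edges to keep the fields regular). The strain
image then decays strongly with depth (~50-60 % top to bottom) while the
modulus image stays nearly flat (a few %). This demonstration feeds the
theoretical displacements through the anti-aliased Gaussian transfer with
the volumetric component retained: in decaying-stress scenes the pressure
profile is encoded in the tiny dilatations, and the
incompressibility-constrained motion model, which discards them, partly
confuses stress decay with stiffness decay. That coupling is a known
limitation of incompressibility-based displacement models for measured
data in strongly depth-decaying stress fields.

## Numerical choices

* Dof ordering interleaved (x, y), node-major; coordinates x lateral,
  y axial (depth, positive downward); mm and kPa units.
* Forward solves: sparse LU with explicit singularity detection;
  prescribed dofs honored exactly by reduction.
* Modulus solve: dense Cholesky of the projected normal equations (the
  ROI has ≲ 4 × 10³ elements); condition estimated by power/inverse
  iteration, with an explicit error above 10¹².
* Spline fits: exact SVD least squares; empty knot cells raise an error
  naming the cells.
* Incompressibility correction: constraint normal equations via sparse
  LU, LSQR fallback; residual verified < 10⁻⁹.
* Default problem sizes: 63 × 63-element ROI (30.24 mm square) centered
  in the phantom; forward mesh 320 × 320 elements; four applied strains.
  These sizes reproduce the study at desk scale; enlarging them changes
  runtimes, not conclusions.

## What the synthetic tests do and do not show

The generator shares its elasticity model (and, deliberately, its
linear-elastic assumptions) with the inversion; passing tests therefore
validate the estimation chain — tracking noise, spline conditioning,
mesh discrepancy between a 4×-finer forward solution and the inversion
elements, ring placement — not the adequacy of linear plane-strain
elasticity for real tissue. Out-of-plane motion, attenuation,
viscoelasticity, nonlinearity at larger strains and transducer-specific
beam physics are all absent. The modulus scale is relative by
construction; absolute calibration would require boundary stress.

## Known limitations

* The reconstruction smooths the inclusion/background interface (knot
  spacing ≈ 4.8 mm), so small inclusions are reported with reduced
  contrast; the mean relative error is negative for stiff inclusions.
* Reconstructed values can be non-positive in noisy corners; they are
  reported as-is with a warning.
* The incompressibility-derived lateral field discards the volumetric
  readout of pressure; in strongly depth-decaying stress fields this
  couples stress decay into the modulus image (see above).
* The tracker is a simple NCC block matcher; pathological decorrelation
  (out-of-plane motion, large shear) is outside its envelope.
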