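# Methods

This note documents the models, numerical choices and limitations of
`tpmphantom`: what exactly is simulated, which defaults encode the
phantom design, and what the passing tests do and do not demonstrate.

## 1. Phantom generator

### Geometry

The scattering region is a cube (default 60 × 60 × 40 µm) of straight
rods with rectangular cross-section 0.5 µm (width) × 1.8 µm (height).
Within a layer all rods are parallel; consecutive layers alternate
between x- and y-alignment and are stacked every 1.4 µm starting at
z = rod_height/2, so no rod protrudes from the cube (28 full layers in
the default cube). Edge-to-edge gaps between neighbouring rods are
i.i.d. Uniform(0.7, 3.0) µm. We read the design's "lateral distance
between rods" as the *edge-to-edge gap*: with 0.5 µm rods this yields a
polymer fill of

  lateral fill = w/(w + E[gap]) = 0.5/2.35 ≈ 0.213,

boosted to ≈ 0.26 by the 0.4 µm vertical overlap of consecutive layers
(1.8 µm rods every 1.4 µm, orthogonal orientations treated as
independent: 0.714·0.213 + 0.286·(1 − (1 − 0.213)²) ≈ 0.26) — matching
the nominal "roughly 25 %" fill factor. The centre-to-centre reading
would give ≈ 35 % and is rejected.

The cell-like target is a truncated ellipsoid (default 30 × 25 × 12 µm,
bottom 10 % of its height cut flat, substrate side) centred in the
cube. It carries, in feature-precedence order (highest wins where
regions overlap): nucleoli (spheres), nucleus (ellipsoid), resolution
line groups, a linear RI gradient box, and cytoplasm. Line groups are
bars of width = half period at frequencies {417, 595, 833, 1190, 1667}
lp/mm laid out coarse-to-fine along x (a geometric-like series chosen
so the printed 1667 lp/mm maximum is the finest group; the sub-maximum
frequencies are a design choice of this package). Rod voxels within
0.5 µm (Euclidean distance transform) of any cell voxel are suppressed;
cell RI overwrites rods.

### Refractive index

All RI offsets are relative to the immersion medium n = 1.5123 (the
index oil the printed structure is immersed in). The absolute polymer
RI is not part of the design; the generator uses
n_background + ΔRI_max = 1.5423 by default (configurable), preserving
the stated maximal contrast ΔRI = 0.03. Internal cell levels default to
cytoplasm 0.010, nucleus 0.015, nucleoli 0.030, bars 0.025, gradient
ramp 0 → 0.020 — distinct levels spanning (0, 0.03], chosen by this
package; any level may be overridden but must stay within ΔRI_max.

### Voxelization

Voxel-centre-inside test on half-open intervals, no anti-aliasing:
geometry is exact and countable (a 0.5 × 1.8 µm rod at 0.1 µm pitch is
exactly 5 × 18 voxels for any sub-voxel offset). Axis order (x, y, z),
z the optical axis; voxel i is centred at origin + (i + 0.5)·pitch.
Default full-scale pitch is 0.1 µm.

### Desk-scale fixtures

The test suite uses a reduced phantom: the cube shrinks to 12 µm and
the cell target scales proportionally, but the rod cross-section, gap
statistics and layer pitch are kept at full-design values so the
microstructure remains resolvable at the 0.25 µm fixture pitch
(uniformly scaling *all* lengths would shrink rods below the
rasterizer's sampling precondition). The cube is embedded centred in a
16 µm field of view of immersion medium — a phantom surrounded by oil,
which also gives the object-support constraint of GPSC genuine
leverage. ΔRI is never scaled with geometry; the weak-scattering
configuration instead reduces ΔRI_max to 0.005 (all internal levels
scaled proportionally).

## 2. Forward model

Multi-slice beam propagation: the volume is a stack of one-voxel-thick
phase screens separated by exact angular-spectrum propagation through
homogeneous immersion medium. The per-slice screen is
exp(i 2π Δn t/λ) with t = dz/cosθ, the slant path of the tilted carrier
through the slice — exact for a homogeneous medium at any tilt, and
required for the simulated data to satisfy the Fourier Diffraction
Theorem to first order at the 47° zenith angle. Propagation kernels
attenuate evanescent components for either propagation direction.

Illumination is a plane wave whose transverse frequency is snapped to
the DFT grid of the lateral window (the effective direction is recorded
per projection and used downstream), making plane-wave propagation
exact and the empty-volume output identically 1. Spectral propagation
is *periodic* (no zero padding) by default: with plane-wave
illumination and screens spanning the full window, zero padding would
introduce aperture diffraction that breaks the plane-wave and
homogeneous-slab closed forms; wrap-around of scattered light is the
standard trade of periodic split-step simulation. Padding remains
available (`pad_factor`).

Fields are referenced to the volume mid-plane (free-space
backpropagation from the exit face) and normalised by the analytic
incident wave, so the stored quantity is the total/incident ratio; the
detector-side pupil applies a hard low-pass at NA/λ (toggleable). The
zenith angle is defined inside the immersion medium; the physical
camera/magnification chain is not modelled — the grid lives in sample
space. Note the grid band limit: at 0.25 µm pitch and λ = 633 nm the
lateral Nyquist (12.6 rad/µm) lies below the full NA cutoff
(12.9 rad/µm) and the medium wavenumber (15.0 rad/µm); the simulated
and reconstructed band is limited by the grid in that regime, and
illumination carriers at or beyond Nyquist are rejected.

Phase noise emulating the interferometric noise floor multiplies every
pixel by exp(iη), η ~ N(0, σ²) i.i.d.; σ = 0.10 rad reproduces the
visible-wavelength (633 nm) dataset noise level, σ = 0.08 rad the
near-infrared (835 nm) one.

## 3. Direct Inversion (Wolf transform)

Per projection the normalised field d is linearised with the Rytov
transform ψ = ln d (amplitude floored at 1e-6 of the peak, phase
unwrapped with the reliability-sorting 2D unwrapper, global 2π offset
fixed on the field border). The Fourier Diffraction Theorem places

  F(K) = −2 i q_z · FT₂[u₀ψ](q),  K = (q⊥ − k s₀⊥, q_z − k s₀ᵤ),
  q_z = √(k² − |q⊥|²),

on the Ewald cap of each projection (k the medium wavenumber, s₀ the
effective illumination direction, detector plane = coordinate z = 0).
Gridding is nearest-voxel with hit-count averaging — chosen over
trilinear spreading because it makes the replenishment constraint
exactly idempotent. Because the scattering potential of a lossless
object is real, every sample is also deposited conjugated at −K
(Hermitian symmetrization); this keeps the accumulated spectrum
consistent with the real volume the GP loop iterates on and roughly
doubles coverage. Δn = Re{F⁻¹[F]}/(2 n_m k₀²).

Under the 47° circular scan the coverage leaves the classic missing
double-cone around the axial frequency axis: tests assert the axial
frequency axis is empty away from DC and that a point-like bead
reconstructs axially elongated.

First-order model choice: Rytov rather than Born, the standard choice
for cell-scale phase objects whose total phase delay exceeds 2π.

## 4. GPSC

Support generation: Chambolle–Pock primal-dual TV solve of the
linearised problem (data term = orthonormal-FFT samples on the measured
caps; with weight 0 the iteration converges to the zero-filled
minimum-norm solution, i.e. Direct Inversion), then Otsu binarisation,
largest connected component, optional morphological *closing* (bridges
the pores of the rod lattice so the support outlines the phantom
envelope — 6 voxels = 1.5 µm, half the maximal rod gap, in the test
fixtures), hole filling, and dilation (default 2 voxels). "Strong" and
"weak" TV weights default to 1e-2 and 1e-3 in the normalised units of
the solver.

GP loop, per iteration: (1) frequency-domain replenishment — overwrite
measured frequencies with the averaged measured spectrum; (2) signal
domain — clamp Δn ≥ 0 and zero outside the support. Both steps are
projections onto convex sets, so the recorded data misfit of the
constrained iterate is provably non-increasing; ending on the signal
step guarantees the returned volume satisfies the constraints exactly.
Stopping: median-dynamics rule with ε = 0.02.

GP semi-converges on noisy or strongly scattering data (the replenished
caps then conflict with nonnegativity and realness, and continued
iteration pumps the inconsistency into the unmeasured region) — the
reason the stopping criterion matters. The error-reduction claim GPSC ≤
Direct Inversion is therefore established on noise-free weak-contrast
data with an envelope support; on the full-contrast noisy configuration
GPSC is *not* expected to win, which is precisely the phantom's point.

## 5. MSBP-E / MSBP-I

Learning-Tomography loop: sequential per-projection gradient steps in
fixed cyclic order (one forward + one adjoint pass per projection), a
TV proximal step (Chambolle dual projection, 20 inner iterations) after
each full cycle, then an optional nonnegativity projection on Δn
(default on — consistent with the phantom's physics). The gradient is
the exact adjoint of the discrete forward chain (verified against
central finite differences to ~1e-8 relative); the adjoint of a
propagation step is propagation by the negated distance with the same
evanescent damping.

Step size: Δn-update = step_size/(γ² n_z) per projection with
γ = 2π dz/λ, i.e. a dimensionless relaxation (default 0.5) of a
Landweber-type bound for the linearised single-projection operator;
halved whenever a cycle's misfit increases, with 20 consecutive
increases raising an error. TV weight default 1e-4 in RI units.
Field mode initialises from Direct Inversion, intensity mode from
zeros; intensity mode uses the amplitude (not squared-intensity) misfit
and is invariant to any global phase of the data. Stopping: ε = 0.01.

## 6. Stopping criterion

d_k = ‖x_k − x_{k−1}‖₂ / ‖x_1 − x_0‖₂; stop when the median of the last
10 values falls below ε. Normalising by the first step makes ε
scale-free across algorithms and RI scales; this normalisation is this
package's concrete choice for the published intent ("dynamics of the
change … drops below a saturation level"). Never stops before 10
recorded iterations; even-length medians are the midpoint of the two
central order statistics. A numerically-zero first step (input already
a fixed point) defines all dynamics as 0, so such runs stop as soon as
the window fills.

## 7. Evaluation protocol

Cross-section profiles average 2·halfwidth+1 rows/columns (halfwidth 4,
i.e. ±4 pixels) around a cut line and report mean ± std per position.
The resolved-frequency readout samples a profile at each group's bar
centres and at the midpoints between bars and computes the Michelson
contrast (peak − trough)/(peak + trough) on Δn above background; a
group is resolved at contrast ≥ 0.1 (the printed design is assessed
visually; 0.1 is this package's operational threshold). The phase-noise
σ estimator unwraps the phase of an object-free region, removes the
best-fit plane (piston + tilt — the residual off-axis carrier would
otherwise dominate) and averages the residual std over projections.

## 8. Test oracles and their limits

- Analytic: slab phase (optical path length), tilted plane-wave
  propagation, Beer–Lambert transmittance, voxel-counting geometry.
- Brute-force first Born: direct summation of G(r−r′)f(r′)u₀(r′) over
  source voxels. MSBP agrees with it to ≤1 % relative RMS for weak
  band-limited objects (Gaussian blob, Δn = 5·10⁻⁴); the residual
  disagreement grows *linearly* with Δn because it is dominated by the
  double-scattering term that first Born itself omits, so the
  comparison is meaningful only in the genuinely weak regime. The
  oracle's detector plane matters: combining steep-zenith projections
  requires sampling just above the object, before obliquely scattered
  light walks off the finite lateral window.
- Enumeration: stopping-rule medians, uniform-gap KS test.

What the synthetic tests do **not** show: real data contain aberrations,
spatially correlated (speckle-like) noise, field-of-view vignetting,
fabrication deviations from the nominal geometry and polymer RI
dispersion — none of which are modelled. Passing here demonstrates
algorithmic correctness and the qualitative physics (missing cone,
regularisation trade-offs, intensity-only low-frequency artifacts), not
instrument-level accuracy.

## 9. Problem sizes

Test fixtures run the full pipeline at 64³ voxels (16 µm FOV at
0.25 µm) with 45 projections at 8° azimuth spacing (a full turn, as in
the 180 × 2° design but coarser), and the design-figure script builds
the full-size cube at 0.2 µm pitch (300 × 300 × 200 voxels, 5 seeds).
These sizes were chosen so the whole suite completes in minutes on a
single CPU while every asserted property is size-stable.
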