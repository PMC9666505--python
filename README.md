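# tpmphantom

A toolkit for benchmarking tomographic phase microscopy (TPM)
reconstruction algorithms against a procedurally generated 3D
biomimetic scattering microphantom.

TPM reconstructs a sample's 3D refractive index (RI) — a proxy for dry
mass in cells — from complex optical fields measured under many
illumination angles. Its reconstruction algorithms fall into two camps:
weak-scattering methods built on the Fourier Diffraction Theorem, and
multiple-scattering methods built on nonconvex optimisation through a
multi-slice beam-propagation (MSBP) model. Deciding which camp applies
to a given sample requires a test object of *known* RI whose structural
complexity matches real tissue. This package generates such an object
as a ground-truth voxel volume, simulates its limited-angle circular-scan
measurement, and reconstructs it with the three algorithms commonly
compared on such targets — so the whole evaluation loop runs on a desk,
with no microscope.

**Who it is for:** developers of TPM / optical diffraction tomography
reconstruction methods who need a controlled, quantitative benchmark,
and phantom designers exploring how fill factor, RI contrast and
feature geometry translate into scattering difficulty.

## The phantom

A 60 × 60 × 40 µm cube of pseudo-randomly spaced rectangular rods
(0.5 × 1.8 µm cross-section; edge-to-edge gaps uniform in 0.7–3 µm;
layers stacked every 1.4 µm with alternating orientation; polymer fill
factor ≈ 25 %), surrounding a cell-like imaging target: a truncated
ellipsoid (30 × 25 × 12 µm) containing bar resolution groups up to
1667 lp/mm (0.6 µm period), nucleoli suspended in a nucleus, and a
region of slow RI variation. Rods are suppressed within 0.5 µm of the
cell target. RI offsets stay within ΔRI ≤ 0.03 of the immersion medium
(n = 1.5123).

## The algorithms

- **Direct Inversion** (Wolf transform): Rytov-linearised fields mapped
  onto Ewald-sphere caps via the Fourier Diffraction Theorem,
  `F(K) = −2i q_z · FT₂[u₀ ψ_R]` on the cap `K = q − k s₀`, averaged and
  inverse-transformed.
- **GPSC** — Gerchberg–Papoulis with support constraint: alternating
  projections between the measured frequency caps (replenishment) and
  the signal-domain constraints Δn ≥ 0 and finite object support (the
  support comes from a strongly TV-regularised Chambolle–Pock
  initial reconstruction, binarised).
- **MSBP-E** — Learning-Tomography loop: gradient descent on
  `Σ‖MSBP(n) − u_meas‖²`, backpropagating the residual through the
  slice stack (exact adjoint), sequential per-projection updates, weak
  TV proximal step per cycle, Direct Inversion initial guess.
- **MSBP-I** — the amplitude-only variant: misfit
  `Σ(|MSBP(n)| − |u_meas|)²`, starting from zeros.

All three share the stopping rule: iterate until the median of the last
10 relative update norms `d_k = ‖x_k − x_{k−1}‖/‖x_1 − x_0‖` drops
below ε (0.02 for GPSC, 0.01 for the MSBP variants).

## Worked example

```python
import dataclasses
from tpmphantom import *
from tpmphantom.geometry import pad_volume
from tpmphantom.msbp import MsbpSettings, msbp_reconstruct

# desk-scale phantom: 12 µm cube, full design microstructure, in a 16 µm FOV
spec = dataclasses.replace(PhantomSpec(), cube_size=(12., 12., 12.))
cspec = CellTargetSpec(ellipsoid_size=(6., 5., 2.4),
                       line_group_frequencies=(833., 1190., 1667.),
                       bars_per_group=3, bar_length=1.0, bar_thickness=0.8,
                       line_row_y=-1.2, group_margin=0.4,
                       nucleus_center=(0., 1.4, 0.), nucleus_semiaxes=(1.2, 1., .8),
                       nucleoli_centers=((-0.5, 1.4, -0.2), (0.5, 1.4, 0.3)),
                       nucleoli_radii=(0.35, 0.35),
                       gradient_center=(-1.8, 0.1, 0.), gradient_size=(1.2, 1., 1.))
truth = pad_volume(generate_phantom(spec, cspec, voxel_pitch=0.25, seed=11),
                   (64, 64, 64), spec.n_background)
fill = compute_fill_factor(truth, region=((0, 12.), (0, 12.), (0, 12.)),
                           n_background=spec.n_background)
print("structure fill over the cube:", round(fill, 3))

cfg = OpticalConfig(wavelength_nm=633., zenith_deg=47.,
                    n_projections=45, azimuth_step_deg=8.)
pset = add_phase_noise(simulate_projection_set(truth, cfg), 0.10, seed=5)

obj = truth.values > spec.n_background + 1e-12
di, cov = direct_inversion(pset)
smooth = tv_initial_reconstruction(pset, tv_weight=1e-2, coverage=cov, di_volume=di)
support = make_support(smooth, dilation=2, closing=6)
gp, hist = gpsc_reconstruct(pset, support, eps=0.02, init=di, coverage=cov)
msbp_e, _ = msbp_reconstruct(pset, MsbpSettings(mode="field", max_iter=25))

for name, rec in [("Direct Inversion", di), ("GPSC", gp), ("MSBP-E", msbp_e)]:
    rmse, bias = ri_error_metrics(rec, truth, obj)
    print(f"{name:17s} RMSE {rmse:.4f}  bias {bias:+.4f}")
```

Output:

```
structure fill over the cube: 0.265
Direct Inversion  RMSE 0.0100  bias -0.0071
GPSC              RMSE 0.0106  bias -0.0040
MSBP-E            RMSE 0.0055  bias -0.0021
```

The fill fraction (rods plus cell target over the 12 µm cube) lands on
the ≈ 25 % design figure. The multiple-scattering method wins at this
contrast — the phantom at full ΔRI = 0.03 and 633 nm is deliberately
beyond the weak-scattering regime; GPSC narrows the bias but only
overtakes Direct Inversion when the contrast (and hence the scattering
strength) is reduced.

The same pipeline is available from the shell:

```bash
phantom generate --seed 7 --pitch 0.1 --out phantom.h5
phantom simulate --phantom phantom.h5 --wavelength 633 --noise-sigma 0.10 \
        --seed 1 --out proj633.h5
phantom reconstruct gpsc --data proj633.h5 --eps 0.02 --out recon.h5 \
        --report run.json
phantom evaluate --recon recon.h5 --truth phantom.h5 --report eval.json
```

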