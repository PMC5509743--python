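# xdflow

Multi-dimensional ("XD") flow MRI reconstruction and quantification on a
built-in dynamic digital phantom.

Volumetric phase-contrast MRI (4D flow) measures time-resolved 3-D blood
velocities, but a 5–15 min scan is corrupted by respiration, bulk patient
motion, and contrast dynamics, and it discards the physiology hidden in
those "nuisance" dimensions.  `xdflow` takes the opposite approach: a
single velocity-encoded Cartesian acquisition, pseudo-randomly subsampled
with a golden-angle variable-density radial view order (VDRad), is
retrospectively **binned** along contrast time *t*, cardiac phase *c*, and
respiratory phase *r*, and reconstructed by weighted compressed sensing

```
m* = argmin_m  ½‖W(Am − y)‖² + λx‖Ψm‖₁ + λt‖Dt m‖₁ + λc‖Dc m‖₁ + λr‖Dr m‖₁
```

where `A` is coils × FFT × subsampling, `W` holds soft-gating/binning
weights (Hanning bin windows × exponential motion down-weighting,
`w_d = e^{−α(d−β)}` for `d > β`), `Ψ` is an orthonormal Daubechies-4
wavelet and `D_*` are finite differences along the extra dimensions.  The
solver is ADMM.  One raw dataset yields, without rescanning:

* **R1** — a few temporal windows with many cardiac phases (motion/contrast
  robustness for high-resolution flow);
* **R2** — respiratory- and cardiac-resolved flow (how breathing modulates
  venous return);
* **R3** — ~2-s temporal frames with few cardiac phases (contrast dynamics
  and perfusion: PBV, PBF, MTT via truncated-SVD deconvolution, linked by
  the central volume theorem MTT = 60·PBV/PBF);
* a conventional soft-gated 4D flow comparator.

Motion comes for free from intrinsic (Butterfly-style) navigators — the
velocity-encoding gradients replay the same central k-space lines every
TR — processed into displacement, respiratory triggers/phase, and
soft-gating weights.  Image sharpness is scored by gradient entropy as a
function of retrospectively lowered resolution.

Since no public raw datasets exist for this acquisition, the package ships
a dynamic digital cardiopulmonary phantom (beating chamber, breathing
liver/diaphragm, pulsatile parabolic vessel flow encoded as phase,
gamma-variate contrast enhancement, multi-coil k-space with navigators and
noise) that provides analytic ground truth for every stage.  It is
first-class, tested code — not a fixture.

## Worked example

```python
import numpy as np
import xdflow as x

cfg = x.PhantomConfig(
    grid_size=48, n_coils=6, scan_duration_s=120.0, TR_ms=4.0,
    vessel=x.VesselSpec(radius_mm=9.0, peak_velocity=80.0, pulsatility=0.3),
    seed=42)
phantom = x.make_phantom(cfg)

order = x.build_view_order((48, 48), n_cardiac=4, n_echoes=4,
                           spokes_per_mask=120, density_exponent=0.3)
table = x.simulate_acquisition(phantom, order)

signals = x.extract_physio(table)
spec = x.BinSpec.for_mode("R1", n_t=2, n_c=4)
binned = x.bin_and_consolidate(table, signals, spec, x.GatingParams())

maps = x.calibrate_sensitivities(table, calib_size=20)
image = x.solve(binned, maps,
                x.ReconConfig(lambda_c=1e-3, lambda_t=1e-3, max_iters=15))

vel = x.decode_velocity(image.data, cfg.venc, bins=image.bins)
vel = x.background_correct(vel, phantom.static_mask())
res = x.roi_flow(vel, phantom.vessel_roi(), cfg.voxel_size_mm ** 2)
print("net flow per cardiac bin (mL/s):",
      np.round(res.flow_ml_s.mean(axis=(0, 2)), 1))
print("analytic ground truth  (mL/s):",
      np.round(phantom.true_flow(np.arange(4) / 4), 1))
print(f"mean flow {res.mean_flow_l_min:.2f} L/min, "
      f"peak speed {res.peak_speed_cm_s:.1f} cm/s")
```

prints

```
net flow per cardiac bin (mL/s): [72.  84.5 97.1 84.2]
analytic ground truth  (mL/s): [ 71.3  86.5 101.8  86.5]
mean flow 5.07 L/min, peak speed 76.4 cm/s
```

The four cardiac bins trace the pulsatile waveform; recovered net flow
tracks the analytic truth (mean error ~2%, the systolic bin slightly
smoothed by the cardiac binning window), and the peak speed approaches the
80 cm/s centerline velocity.

The same stages are available from a shell:

```bash
xdflow simulate --out raw.h5 --grid 48 --coils 6 --duration 120 --seed 42
xdflow physio raw.h5 --out physio.h5
xdflow bin raw.h5 --physio physio.h5 --mode R1 --out binned.h5
xdflow recon binned.h5 --out recon.nii
xdflow sharpness recon.nii --factors 1,1.5,2,3,4
xdflow run config.yaml --out results/    # whole pipeline from a YAML config
```

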