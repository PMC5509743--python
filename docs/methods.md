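# Methods

`xdflow` implements a multi-dimensional ("XD") flow MRI reconstruction
pipeline: a single velocity-encoded Cartesian acquisition, pseudo-randomly
subsampled with a variable-density radial view order, is retrospectively
binned along contrast time *t*, cardiac phase *c*, and respiratory phase
*r*, and each velocity-encoding echo *f* is reconstructed by weighted
compressed sensing.  From the reconstructed image set the package
quantifies blood flow (phase-contrast velocimetry), contrast dynamics
(indicator-dilution perfusion), and image sharpness.  Everything runs on a
built-in dynamic digital phantom that supplies ground truth.

## The reconstruction model

Per echo, the image set `m` over the active extra dimensions solves

```
m* = argmin_m  1/2 ||W (A m - y)||^2
              + lambda_x ||Psi m||_1 + lambda_t ||D_t m||_1
              + lambda_c ||D_c m||_1 + lambda_r ||D_r m||_1
```

* `A` applies per-coil sensitivity maps, a unitary centered 2-D FFT, and
  each bin's sampling pattern.  The unitary normalization makes `A`'s
  spectral norm approximately the sensitivity-map norm, so regularization
  weights transfer across grid sizes.
* `W` carries the soft-gating/binning weights (below), one scalar per
  consolidated sample.
* `Psi` is the orthonormal 2-D Daubechies-4 wavelet transform of each
  spatial slice, in periodized form.  Periodization was chosen over
  symmetric extension because it is the only boundary rule that keeps the
  transform square and orthogonal (`||Psi x|| = ||x||`, exact round trip),
  which in turn keeps the ADMM subproblems exactly solvable by
  soft-thresholding.
* `D_t, D_c, D_r` are first-order finite differences.  The cardiac
  difference is cyclic (cardiac phase is periodic; the flag
  `ReconConfig.cyclic_cardiac` disables it); `t` and `r` use forward
  differences with a replicated edge, so a constant array is always in the
  null space.

The solver is ADMM with one split variable `z_i = T_i m` per active
regularizer.  The x-update solves the Hermitian positive-definite normal
equations with conjugate gradients (default 10 inner iterations); each
z-update is a complex soft-threshold; convergence is declared when both the
primal residuals `||T_i m - z_i||` and the dual residuals
`rho ||z_i - z_i_prev||` fall below `tolerance * ||m||`.  A naive
"x stopped moving" rule is wrong here: with well-conditioned data the very
first x-update is already stationary while the duals have not moved at all.
The data are rescaled so the peak of `A^H W^2 y` is 1 before solving (and
rescaled back after), which makes the lambda values meaningful across
problem sizes.

Default starting weights are `lambda_x = 1e-5` for the wavelet and `0.01`
for each finite difference, and they are meant to be tuned per
reconstruction type; the noiseless desk-scale studies in
`xdflow.experiments` use `1e-3` for the finite differences because at
`0.01` the cardiac total variation visibly flattens the systolic peak
(about 8% at six cardiac bins), which matters when the quantity of interest
is peak flow.  `admm_rho` defaults to 0.1; in the hard-constraint regime
(very large lambda) rho should be raised to the same order as lambda or the
dual ascent is slow.

Empty bins contribute no data term and are recovered purely through the
finite-difference coupling to their neighbors — this is the point of
reconstructing in the higher-dimensional space rather than gating data
away.

## Sampling design

Phase-encode views on the (ky, kz) grid are grouped into center-out spokes
whose radial step grows as `(1 + r)^p` (`p` = `density_exponent`, so
density falls off like `r^-p`); spokes are ordered by the golden-ratio
angle increment 137.5078 deg and dealt round-robin across the
`N_c x N_e` sampling masks.  Two non-obvious choices:

* Every spoke starts its radius sequence at a sub-step offset hashed from
  the angle by the golden ratio.  Without this, all spokes share one
  radius sequence and the union of masks leaves entire annuli unsampled —
  in particular the calibration region never fills.  Hashing (rather than
  using the angle fraction directly) matters because angular neighbors are
  the only spokes able to cover a given cell, and they must disagree about
  radii.
* Grid indices are 0-based with DC at `N // 2` on each axis; this single
  convention is used by every k-space array in the package.

The reduction factor `R` is the grid size over the number of unique
sampled views; combining adjacent masks is monotonically non-increasing in
`R` (tested as a property).

## Physiologic signal chain

Navigator readouts (the central k-space line along each axis, replayed
every TR by the velocity-encoding gradients) are turned into motion
signals in six steps: per-coil/per-axis displacement by a
magnitude-weighted lag-one phase-difference fit (robust to wrapping for
multi-pixel shifts); zero-phase low-pass at 95% of the heart rate;
zero-phase high-pass at 0.1 Hz; correlation clustering across coils
(threshold 0.9, largest connected component, sign-aligned to the seed
coil, mean); normalization of the displacement norm by its standard
deviation (`d1`, population std, so `std(d1) = 1`); histogram centering on
the most occupied of 64 bins (ties toward smaller `d1`).

Filter design: the low-pass stages are 4th-order Chebyshev-II run
forward-backward, so the named cutoff is a true stopband edge (>= 30 dB,
doubled by the zero-phase pass).  A Butterworth of the same order cannot
attenuate a component only 5% above its cutoff, which is exactly the
margin the 95%-of-heart-rate rule implies.  The drift high-pass is
Butterworth because it needs an exact DC null, not a sharp transition.

The respiratory rate is estimated from the autocorrelation peak rather
than the FFT peak: `d1` is a norm and therefore rectified, which injects a
strong second harmonic; the true period still dominates the
autocorrelation whenever the breathing waveform is asymmetric (which real
breathing, and the phantom's raised-cosine-power waveform, is).
Respiratory triggers are maxima of `d` (end-inspiration) with minimum
separation half the estimated period and an edge guard against the
zero-phase filters' transients; respiratory phase is the linear position
in time between enclosing triggers.  The trigger polarity is a flag.
Cardiac phase is taken from the acquisition table's trigger stamps.

If the displacement norm has zero variance the record is flagged
motion-free and `d1` is defined as 0, so downstream weighting treats every
sample as uncorrupted.

## Binning weights and consolidation

Each readout receives a Hanning weight per resolved dimension — 1 at its
bin center, 0 at the adjacent center, cos^2 in between, so adjacent bins
partition unity — times an exponential motion down-weight
`w_d = exp(-alpha (d - beta))` for `d > beta` (else 1), with
`alpha = 1.0`, `beta = 0.25`.  Cardiac and respiratory distances are
cyclic.  A dimension with a single bin gets weight 1 (it is simply not
resolved).  When respiration is resolved the motion down-weight is
dropped; when it is soft-gated the respiratory Hanning weight is dropped.
Samples with composed weight below 1e-6 are discarded.

Repeated samples of one (ky, kz, bin) cell are consolidated:
`value = sum(w^2 y) / sum(w^2)`, `weight = sqrt(sum w^2)`.  This changes
the weighted least-squares data term only by a constant independent of the
image (zero when duplicates carry equal values), so the minimizer — and
hence the reconstruction — is unchanged while memory shrinks; both facts
are verified numerically.

In the high-temporal-resolution contrast mode (R3), only echo 0 is
reconstructed and samples from the other echoes are folded into it with an
extra factor 0.5.

## Calibration and coil handling

Sensitivity maps are estimated once per dataset from the echo-0 data
projected (averaged) into a single k-space volume; the variable-density
center oversampling guarantees the central calibration region (default
24 x 24) is fully covered, and an uncovered point is an error naming the
missing extent.  The maps come from the eigenvector method: block-Hankel
calibration matrix from sliding k-space patches (kernel scaled to at most
a third of the region), SVD-thresholded kernels (2% of the top singular
value), per-voxel dominant eigenvector of the image-domain kernel
operator, phase referenced to coil 0, cropped where the top eigenvalue is
below 0.8.  Low-resolution ratio maps (apodized central k-space over
root-sum-of-squares) are the fallback, selected automatically when the
calibration region is too small to support the kernel statistics.  Coil
compression is a global SVD to (by default) 6 virtual coils, with the
retained energy fraction reported.

## Flow quantification

Velocities are decoded per voxel from phase differences against the
flow-compensated reference echo; the simple referenced four-point
encoding matrix is the default and any rank-4 matrix is accepted.  Using
differences cancels anatomical/background object phase without
unwrapping; the phantom respects `|v| < VENC`, and aliased voxels are
flagged, not unwrapped.  Background phase is removed by a third-order
polynomial fitted over static-tissue voxels on the time-averaged velocity
and subtracted from every bin; the fit refuses to run with fewer voxels
than coefficients.  Static tissue must be spatially distributed — a small
isolated patch lets a cubic extrapolate wildly at the vessel, which is a
property of polynomial fitting, not of the data.  ROI flow is the sum of
the normal velocity component times pixel area (cm/s x cm^2 = mL/s);
velocity noise is the static-tissue standard deviation at the cardiac bin
nearest normalized phase 0.75.

## Perfusion quantification

Tissue enhancement is modeled as the arterial input function convolved
with a scaled residue `F R(t)`.  Deconvolution is truncated SVD of the
lower-triangular convolution matrix; the matrix uses trapezoid-rule
(Volterra) quadrature — endpoint samples halved — because the rectangle
rule biases the recovered residue peak by O(dt/2), which at 2-s frames and
4-s transit times is a 25% error in the mean transit time.  PBV is 100
times the trapezoid integral ratio of tissue to AIF, PBF is
`100 * 60 * max_t F R(t)` (negative peaks clipped for maps; the raw
residue is returned), and MTT = 60 PBV / PBF, so the central volume
theorem holds identically by construction.  The truncation threshold
defaults to 0.15 of the top singular value (appropriate for clinical
noise); the right setting scales with the noise level, roughly 1/SNR, and
the SNR-50 validation study uses 0.02.  A threshold of exactly 0 means "no
truncation beyond machine precision" (floor 1e-10).  Signal is assumed
proportional to concentration; no relaxivity or linearity correction is
applied.

## Sharpness metric

Gradient entropy: forward-difference gradient magnitudes of the magnitude
image, normalized to a distribution, Shannon entropy (natural log; the
base only scales the metric).  Lower is sharper; a constant image is
defined as 0.  The resolution curve retrospectively lowers the in-plane
resolution by hard-cropping central k-space at factors {1, 1.5, 2, 3, 4}
(an apodized window is a flag) and evaluates the entropy on a single
slice, since Cartesian subsampling only affects the phase-encode plane.
The entropy minimum estimates the true underlying resolution — but only
in the presence of some structureless high-frequency energy (noise): on a
strictly noiseless band-limited image the curve is flat beyond the true
resolution and the minimum is not meaningful.  The validation experiment
therefore includes a 1%-of-peak noise floor.

## The digital phantom

A planar (y, z) scene of soft-edged ellipses: body, liver (translates
along z with respiration; its dome is the "diaphragm"), a cardiac chamber
(radius contracts by a configurable fraction through the cycle), a
static-tissue block, and a circular vessel with parabolic through-plane
flow encoded as phase (`phase = pi v / VENC` per encoding direction).
Pulsatility scales the centerline velocity by
`(1 - p) + p sin^2(pi c)`; respiration can modulate flow by
`1 + q cos(2 pi r)` (venous return increases during inspiration).  Tissue
signal follows a gamma-variate enhancement curve with optional
recirculation bump.  Respiratory displacement follows a raised cosine to a
configurable power (default 2), reproducing the end-expiratory dwell of
real breathing; bulk motion is a list of step displacement events along y.
Complex Gaussian noise is added in k-space relative to the peak object
signal.  Coil sensitivities are smooth Gaussian-profile maps normalized to
unit root-sum-of-squares per voxel.

The simulator plays the view order prospectively: at TR `n` the echo is
`n mod N_e`, the cardiac mask bin is looked up from the instantaneous
cardiac phase, and the next unacquired sample of that mask is collected,
cycling when the mask is exhausted — which is what produces the repeated
samples the consolidation rule averages.  The object state is quantized
(64 cardiac states, 32 respiratory states, 1/8-pixel bulk steps, 0.5-s
enhancement frames) so each distinct state is rendered and Fourier
transformed once; every k-space sample equals the DFT of the coil-weighted
instantaneous image to float precision (tested against a direct DFT
oracle).  Navigators are the central k-space lines along both axes of the
same coil k-space, so they inherit the true displacement as linear phase.

What the phantom does not emulate: relaxation and off-resonance, Maxwell
phase, gradient nonlinearity, non-rigid respiratory deformation (organs
translate rigidly), through-plane motion, and coil sensitivities that move
with the patient.  Consequently, passing tests demonstrate the
correctness of the sampling/gating/reconstruction/quantification chain
under its stated model, not robustness to those physics.  One deliberate
consequence is visible in the tests: a navigator displacement estimate is
biased a few percent low when the object moves through stationary coil
profiles, exactly as in vivo.

## Problem sizes and runtimes

The validation studies are sized for a single CPU: the flow study uses a
64^2 grid, 8 coils, 4 echoes, about 62,000 readouts (R ~ 2.3 per bin);
the respiratory and motion studies use 48^2 grids; perfusion and
sharpness run on curves and single slices.  The complete test suite runs
in about a minute; the acceptance script in about a minute and a half.

## Known limitations

* 2-D (single-slice) objects only; the containers and operators are laid
  out so a third spatial dimension is an extension, not a rewrite, but it
  is not implemented.
* Cardiac self-gating from navigators is out of scope; cardiac phase
  stamps are taken as given.
* The encoding matrix abstracts the gradient waveform design; minimum-TE
  four-point encoding differs only in the matrix, which is pluggable.
* Maxwell-term and gradient-nonlinearity corrections are explicit no-op
  hooks: they require vendor gradient-hardware coefficients.
* No joint multi-dimensional low-rank model; regularizers are separable
  per dimension.
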