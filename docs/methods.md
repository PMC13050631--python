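# Methods

This note documents the models, parameters and numerical choices behind
`spiraldense`, and the limits of what the phantom-based validation can show.

## 1. Numerical phantom

### Geometry and motion

The phantom is an annulus (mid-ventricular short-axis left-ventricle
stand-in) with endocardial radius 20 mm and epicardial radius 32 mm inside a
156 mm field of view. A material point at reference polar coordinates
(R, Theta) moves to

    r(R, t)     = R * (1 - c(t) * w(R)),
    theta(R, t) = Theta + tau(t),
    x(t)        = x_motion(t) + b(t),

where

- `c(t)` is the contraction time course: `sin^2` rise to the peak
  contraction fraction (default 0.15) at end systole (35% of the cycle),
  then a `cos^2` relaxation toward a residual of 30% of peak — real cines
  end before full return to the end-diastolic state;
- `w(R)` is a transmural weight (default constant 1; a linear
  endo-to-epi falloff is configurable);
- `tau(t)` is a bulk twist (default 5 degrees at peak) sharing the
  contraction time course;
- `b(t)` is a rigid in-plane translation (default (1.5, 0.8) mm at peak,
  same time course) standing in for the net cardiac translation seen in
  vivo. Being rigid it contributes displacement — and therefore encoded
  phase — but exactly zero strain, so it leaves the strain oracle intact
  while keeping phase-based metrics (e.g. phase SNR, whose numerator is a
  mean myocardial phase) away from the degenerate zero-mean case that a
  purely concentric contraction produces by symmetry.

Because the twist is independent of R and the translation is rigid, the
circumferential stretch is exactly `lambda = r/R` and the Green–Lagrange
circumferential strain has the closed form

    E_cc = (lambda^2 - 1) / 2,

used as the oracle for the entire analysis chain. The inverse motion map
(needed for Eulerian quantities on the pixel grid) is obtained from a
monotone tabulation of `R -> r(R, t)` on a fine radial grid with linear
interpolation; the tabulation error is well below the strain tolerances
(forward-mapping the recovered reference positions reproduces pixel centers
to < 1e-3 mm).

### Signal model

Per coil c, cardiac phase t, phase cycle p in {0, 1} and encoding
e in {reference, x, y}:

    I_c(x) = S_c(x) * [ A_ste(x, t) * exp(i (2 pi k_e u_e(x, t) + p pi + phi_bg(x)))
                        + A_art(x)   * exp(i phi_bg(x)) ],

with displacement-encoding frequency k_e = 0.10 cycles/mm, a stimulated-echo
amplitude carrying T1 decay (4% per frame) and a ~1-pixel `tanh`-smoothed
annulus edge (limits Gibbs ringing in the k-space simulation), a
T1-recovery artifact echo (Gaussian blob, amplitude 0.3) that does **not**
flip with the phase cycle, and a smooth static background phase. The
encoded displacement is the Eulerian field u(x) = x - X(x): the displacement
of the tissue currently at pixel x relative to its reference position —
the standard DENSE convention.

Coil sensitivities are birdcage-style: Gaussian magnitude falloff from coil
centers on a ring at 1.2 x FOV/2, plus a smooth spatial phase. Defaults
follow the high-resolution protocol the package targets: 128 x 128 matrix,
24 coils, 20 cardiac phases, 2 phase cycles, 3 encodings.

## 2. Acquisition and reconstruction

- **Trajectory**: uniform-density Archimedean spiral, 4 interleaves, 2784
  points per interleaf at matrix 128 (scaled proportionally at other
  sizes), `n_turns = N / (2 N_sp)` so the interleaf set meets the radial
  Nyquist criterion; interleaf m is interleaf 0 rotated by 2 pi m / N_sp.
- **Noise**: complex Gaussian, i.i.d. over k-space samples and array
  dimensions, correlated across coils by a Hermitian positive-definite
  covariance (exponential decay rho^|i-j|, rho = 0.3). The injected level
  for a target apparent SNR is obtained by pushing a unit-variance
  noise-only realisation through the identical whiten/recon/combine path
  and scaling by linearity — not by a closed-form guess.
- **Pre-whitening**: W = L^-1 with L the Cholesky factor of the empirical
  coil covariance from a noise-only prescan; downstream stages then assume
  identity coil covariance (verified to 0.05 in the tests).
- **NUFFT**: Kaiser–Bessel gridding interpolation (width 4, Beatty shape
  parameter) onto a 2x-oversampled grid, implemented as a sparse matrix so
  the forward/adjoint pair is an exact transpose pair (inner-product
  identity at machine precision). Forward accuracy vs. a direct DFT oracle
  is ~1e-3 relative, standard for this kernel/oversampling choice.
- **Density compensation**: analytic ramp |k| with a floor of half a
  k-space cell, normalised so a centered delta reconstructs to peak 1.
  Reconstruction is the density-compensated adjoint (no iterations):
  the denoiser is meant to operate on exactly this kind of recon, whose
  gridding step correlates the image-domain noise.

## 3. Noise bounds and denoising

Overlapping 6D patches (default 3 x 3 in-plane, stride 1, all coil /
phase / cycle / encoding entries) are reshaped into real Casorati-like
matrices. The dimension grouping keeps (x, y) joined by one of
{coil, phase, cycle, encoding} on one side — at full scale the
(x, y, coil) | (phase, encoding, cycle) grouping gives 432 x 120 matrices —
with real and imaginary parts concatenated along the spatial side.

For i.i.d. noise the Gram eigenvalues of a p x q noise matrix concentrate
on the Marchenko–Pastur support [a, b]. Gridded noise is correlated and
non-stationary, so per patch location the package Monte-Carlo-estimates the
ratios r_upper = b_B / b and r_lower = a / a_B over 10 noise-only
acquisitions reconstructed through the same operator instance as the data
(a `CalibrationKey` hash enforces that trajectory, dimensions, patch
geometry, grouping and whitening state all match). At denoising time each
patch supplies its own noise-floor estimate a_B_hat (smallest Gram
eigenvalue) and the chain

    b_B_hat = r_upper * [(1 + sqrt(gamma))^2 / (1 - sqrt(gamma))^2] * r_lower * a_B_hat

yields the local ceiling; singular values at or below sqrt(q * b_B_hat) are
zeroed (hard threshold) and overlapping patches are averaged uniformly.
Consequences verified in the tests: noise-only reconstructions lose ~99% of
their energy, while the noise-free phantom passes through essentially
unchanged (NRMSE ~1e-15) because signal-dominated patches are rank-deficient
and their smallest eigenvalue — hence their threshold — is ~0.

## 4. Strain analysis

Phase cycles are combined as (I_0 - I_1)/2 (cancels the artifact echo
exactly), coils by sensitivity-weighted combination in the whitened basis
(phase-preserving). The x/y-encoded images are referenced to the
unencoded acquisition (removing the static background phase), unwrapped
spatially per frame (masked 2D unwrapping) with a temporal pass that fixes
the global 2 pi offset per frame, and scaled to displacement by
u = delta_phi / (2 pi k_e).

Strain uses F^-1 = I - du/dx on the Eulerian displacement (2 x 2 pixelwise
inversion), E = (F^T F - I)/2, projected on the circumferential direction at
the reference position X = x - u. Spatial derivatives are Gaussian-smoothed
(sigma = 1 px) central differences with mask-normalised convolution so
out-of-wall pixels never contaminate the estimate. Segment statistics use
the six standard 60-degree mid-ventricular sectors; the angular origin
defaults to the phantom's +x axis (in real data the RV insertion angle is
supplied). Empty segments report NaN, not zero.

Noise-free end-to-end accuracy: RMS(E_cc - closed form) ~ 8e-4 inside the
eroded wall at 48–64 pixel grids, an order of magnitude below the 0.01
acceptance tolerance; rigid motion yields |E_cc| < 1e-3.

## 5. Determinism

A single master seed generates per-stage child seeds through
`numpy.random.SeedSequence`; identical configuration + seed reproduces every
array bit-for-bit (tested). All child seeds are < 2^31.

## 6. Limitations

- Validation is entirely synthetic. The phantom's motion is smooth,
  analytic and 2D; there is no through-plane motion, no trabeculation, no
  off-resonance, no gradient-delay error, and the coil model is idealised.
  Conclusions about *relative* behaviour (denoised vs. non-denoised,
  grouping/patch ablations) are the validated claims; absolute SNR or
  strain values on real scans are not.
- The reconstruction is a plain density-compensated adjoint. Iterative or
  parallel-imaging reconstructions would change the noise correlation
  structure; the calibration machinery supports any recon that can be run
  on noise-only inputs, but only the adjoint path is exercised here.
- Hard thresholding with uniform overlap averaging is the only shrinkage
  rule implemented; soft or optimal shrinkage variants are out of scope.
- The per-patch noise-floor estimate a_B_hat assumes the smallest Gram
  eigenvalue is noise-dominated, i.e. the signal rank is strictly below
  min(p, q). Very small patches with extremely high signal complexity
  would violate this; at the implemented patch sizes the phantom (and
  typical cine DENSE redundancy) satisfies it.
- Phase unwrapping is spatial-then-temporal with a global per-frame offset
  correction; pathological wrap topologies (isolated islands with > 2 pi
  discrepancies) are not exercised by the phantom.
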