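# spiraldense

Low-rank denoising, reconstruction and strain analysis for 2D spiral cine
DENSE (Displacement ENcoding with Stimulated Echoes) cardiac MRI, exercised
end-to-end on a synthetic numerical phantom with analytic ground truth.

## The problem

DENSE encodes myocardial tissue displacement into the phase of the stimulated
echo, which carries only about half the signal of a conventional echo.
Pushing spatial resolution therefore quickly runs into noise: displacement
maps become erratic and the circumferential strain (E_cc) derived from them
inherits large, spatially structured errors.

Cine DENSE data are highly redundant across coils, cardiac phases,
phase-cycling repetitions and encoding directions. Stacking small image
patches from this 6-dimensional array into Casorati-like matrices yields
matrices whose signal part is low rank while the noise spreads over all
singular values. If the noise were i.i.d., the Marchenko–Pastur (MP) law
would give a closed-form ceiling for the noise singular values: for a p x q
noise matrix with entry variance sigma^2 and gamma = min(p,q)/max(p,q), the
Gram eigenvalues concentrate on

    [a, b] = [sigma^2 (1 - sqrt(gamma))^2,  sigma^2 (1 + sqrt(gamma))^2],

so zeroing every singular value below sqrt(q*b) removes noise and keeps
signal.

Spiral acquisitions break the i.i.d. premise: the gridding (convolution)
step of the non-Cartesian reconstruction correlates the image-domain noise,
shifting the empirical eigenvalue bounds away from [a, b] in a way that
depends on the trajectory, the coil count and the patch geometry. This
package implements the correction: the empirical bounds a_B, b_B of the
correlated noise relate to the i.i.d. bounds through ratios (b_B/b and
a/a_B) that are estimated once by Monte-Carlo simulation — noise-only
acquisitions pushed through *exactly* the same reconstruction path as the
data. The per-patch threshold is then recovered from the data itself via

    b_B_hat = (b_B/b) * (b/a) * (a/a_B) * a_B_hat,

where a_B_hat is the smallest Gram eigenvalue of the data patch (noise-floor
estimate) and the middle factor is the closed-form MP ratio. No separate
noise scan of the object is needed at denoising time.

## What is in the package

| Module | Contents |
| --- | --- |
| `spiraldense.phantom` | Contracting/twisting annular LV phantom with analytic displacement and E_cc; full 6D DENSE signal model (stimulated echo, T1 artifact, phase cycling, background phase) |
| `spiraldense.sampling` | Archimedean spiral trajectory design, multicoil forward sampling, coil-correlated noise injection |
| `spiraldense.nufft` | Kaiser–Bessel gridding NUFFT with an exact forward/adjoint pair |
| `spiraldense.recon` | Coil noise pre-whitening, ramp density compensation, adjoint-NUFFT reconstruction |
| `spiraldense.bounds` | MP bounds/pdf, eigen-spectra, Monte-Carlo ratio calibration, the threshold chain |
| `spiraldense.denoise` | 6D patch extraction, Casorati reshaping (4 dimension groupings), hard singular-value thresholding with overlap averaging |
| `spiraldense.strain` | Phase-cycle/coil combination, spatiotemporal phase unwrapping, displacement, Green–Lagrange E_cc, AHA segment statistics |
| `spiraldense.metrics` | Apparent SNR, phase SNR, scan efficiency, NRMSE, normalized gradient, Bland–Altman, Wilcoxon signed-rank |
| `spiraldense.pipeline` / `spiraldense.cli` | Seed-deterministic end-to-end runs; `spiraldense` CLI with `simulate`, `calibrate`, `reconstruct`, `denoise`, `analyze`, `run`, `report` |

## Worked example

A full run at a reduced size (64 x 64 grid, 8 coils, 10 cardiac phases; the
default configuration is the full-scale 128 x 128 / 24-coil / 20-phase
protocol) with the injected noise level calibrated so the non-denoised
apparent magnitude SNR lands near 25:

```python
from spiraldense import PhantomConfig, RunConfig, run_pipeline

config = RunConfig(
    phantom=PhantomConfig(grid_size=64, n_coils=8, n_phases=10),
    target_snr=25.0,
    seed=1,
)
result = run_pipeline(config)
for key, value in result.metrics.items():
    print(f"{key:28s} {value:.4f}")
```

Output (seed 1):

```text
sigma                        6.9211
nrmse_noisy                  1.1066
apparent_snr_noisy           24.8356
phase_snr_noisy              3.0849
scan_efficiency_noisy        0.0373
ecc_abs_error_noisy          0.0056
mean_segment_sd_noisy        0.0100
nrmse_denoised               0.2064
apparent_snr_denoised        153.3299
phase_snr_denoised           9.1480
scan_efficiency_denoised     0.2304
ecc_abs_error_denoised       0.0038
mean_segment_sd_denoised     0.0074
calibration_r_upper          1.0097
calibration_r_lower          0.9982
```

Reading the numbers:

- **NRMSE** against the noise-free reference drops from 1.11 to 0.21 — an
  81% relative reduction — while the calibrated ratios stay near 1, i.e. the
  gridding correlation at this trajectory/patch combination is mild but
  measurable.
- **Apparent SNR** rises from 25 to 153 and **phase SNR** from 3.1 to 9.1.
- The mean absolute **E_cc error** against the analytic strain map falls
  from 0.0056 to 0.0038, and the mean segmental E_cc standard deviation from
  0.0100 to 0.0074.

The same run from the command line:

```sh
cat > config.yaml <<'YAML'
phantom: {grid_size: 64, n_coils: 8, n_phases: 10}
target_snr: 25.0
YAML
spiraldense run --config config.yaml --seed 1 --outdir out/
```

which writes `out/metrics.json`, per-segment strain tables
(`strain_noisy.csv`, `strain_denoised.csv`) and an HDF5 container with the
reference/noisy/denoised image stacks and the embedded configuration.

## Reproduction

Everything is deterministic under a single master seed (same seed, same
bits). To reproduce the headline quantities:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full pipeline at the reduced size above plus two standalone
diagnostics (MP spectrum coverage for i.i.d. noise, and the fraction of
energy the calibrated denoiser removes from a noise-only reconstruction,
which lands at 0.988) and writes each quantity with its sample size as JSON.
Runtime is roughly 1–2 minutes on one CPU.

The test suite, including the acceptance criteria (MP coverage, calibration
sanity, noise annihilation, signal preservation, denoising benefit over
seeds, patch/grouping ablation ordering, the strain oracle and
bit-reproducibility), runs with:

```sh
python -m pytest -q tests/
```

(about 2.5 minutes on one CPU).

## Documentation

`docs/methods.md` describes the signal model, the motion model and its
closed-form strain, the numerical choices (gridding kernel, density
compensation, unwrapping, derivative estimation) and the limitations of the
phantom-based validation.
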