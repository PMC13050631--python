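"""Cycle/coil combination, unwrapping, displacement and E_cc computation."""

import numpy as np
import pytest

from spiraldense.phantom import PhantomConfig, render_dense_images
from spiraldense.recon import DenseImageSet
from spiraldense.strain import (
    AHA_MID_SEGMENTS,
    CombinedImages,
    analyze_strain,
    coil_combine,
    combine_phase_cycles,
    compute_ecc,
    displacement_from_combined,
    phase_to_displacement,
    segment_stats,
    unwrap_phase,
)


def _image_set(data):
    return DenseImageSet(images=data, pixel_mm=1.0, ke_cyc_per_mm=0.1)


def test_combine_phase_cycles_cancels_artifact():
    rng = np.random.default_rng(0)
    shape = (6, 6, 2, 3, 1, 3)
    ste = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    art = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    data = np.concatenate([ste + art, -ste + art], axis=4)
    out = combine_phase_cycles(_image_set(data))
    assert np.allclose(out, ste[:, :, :, :, 0, :], atol=1e-12)


def test_combine_single_cycle_is_identity():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((4, 4, 2, 3, 1, 3)) + 0j
    out = combine_phase_cycles(_image_set(data))
    assert np.array_equal(out, data[:, :, :, :, 0, :])


def test_coil_combine_trivials():
    rng = np.random.default_rng(2)
    img = rng.standard_normal((5, 5, 1, 2, 3)) + 1j * rng.standard_normal((5, 5, 1, 2, 3))
    ones = np.ones((5, 5, 1), dtype=complex)
    out = coil_combine(img, ones, 1.0, 0.1)
    assert np.allclose(out.images, img[:, :, 0])  # single flat coil: identity
    # two coils holding (sensitivity-weighted) copies of the same object:
    # the combination removes the sensitivity phase exactly
    obj = img[:, :, 0]
    sens = np.stack([ones[:, :, 0], 1j * ones[:, :, 0]], axis=-1)
    two = np.stack(
        [obj * sens[:, :, 0, None, None], obj * sens[:, :, 1, None, None]], axis=2
    )
    out2 = coil_combine(two, sens, 1.0, 0.1)
    assert np.allclose(out2.images, obj, atol=1e-12)
    with pytest.raises(ValueError):
        coil_combine(two, np.zeros_like(sens), 1.0, 0.1)


def test_combined_phase_equals_ste_phase_with_artifact():
    cfg = PhantomConfig(
        grid_size=32, n_coils=1, n_phases=4, artifact_amplitude=0.4,
    )
    truth = render_dense_images(cfg)
    imgs = DenseImageSet(
        images=truth.reference_images, pixel_mm=cfg.pixel_mm,
        ke_cyc_per_mm=cfg.ke_cyc_per_mm,
    )
    comb = coil_combine(
        combine_phase_cycles(imgs), np.ones((32, 32, 1), dtype=complex),
        cfg.pixel_mm, cfg.ke_cyc_per_mm,
    )
    pure = render_dense_images(
        PhantomConfig(grid_size=32, n_coils=1, n_phases=4, artifact_amplitude=0.0)
    ).reference_images[:, :, 0, :, 0, :]
    sel = np.abs(pure) > 1e-3
    dphi = np.angle(comb.images[sel] * np.conj(pure[sel]))
    assert np.max(np.abs(dphi)) < 1e-6


def test_unwrap_linear_ramp():
    n = 32
    x = np.arange(n, dtype=float)
    true_phase = np.tile(0.6 * x[:, None], (1, n))  # spans ~ 6 pi
    wrapped = np.angle(np.exp(1j * true_phase))
    masks = np.ones((1, n, n), dtype=bool)
    out = unwrap_phase(wrapped[..., None], masks)[..., 0]
    # unwrapped differs from truth by one global 2 pi multiple
    diff = out - true_phase
    assert np.ptp(diff) < 1e-6
    assert np.allclose(diff, 2 * np.pi * np.round(diff / (2 * np.pi)), atol=1e-6)


def test_unwrap_no_wraps_is_identity():
    rng = np.random.default_rng(3)
    phase = 0.3 * rng.standard_normal((8, 8, 2))
    masks = np.ones((2, 8, 8), dtype=bool)
    out = unwrap_phase(phase, masks)
    assert np.allclose(out, phase, atol=1e-9)


def test_unwrap_output_multiple_of_2pi():
    rng = np.random.default_rng(4)
    phase = np.angle(np.exp(1j * 5 * rng.standard_normal((10, 10, 3))))
    masks = np.ones((3, 10, 10), dtype=bool)
    out = unwrap_phase(phase, masks)
    k = (out - phase) / (2 * np.pi)
    assert np.allclose(k, np.round(k), atol=1e-6)


def test_phase_to_displacement():
    assert phase_to_displacement(np.pi, 0.10) == pytest.approx(5.0)
    assert phase_to_displacement(0.0, 0.10) == 0.0
    with pytest.raises(ValueError):
        phase_to_displacement(1.0, 0.0)


def test_compute_ecc_rigid_translation():
    n = 32
    disp = np.zeros((n, n, 2))
    disp[..., 0] = 3.0  # uniform 3 mm translation
    xi, yi = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(xi - n / 2, yi - n / 2)
    mask = (r > 5) & (r < 12)
    ecc = compute_ecc(disp, mask, (n / 2, n / 2), pixel_mm=1.0)
    assert np.nanmax(np.abs(ecc)) < 1e-3


def test_compute_ecc_uniform_contraction():
    # x = 0.9 X -> u(x) = x - X = x (1 - 1/0.9); E_cc = -0.095
    n = 64
    pixel = 1.0
    xi, yi = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x_mm = (xi - n / 2) * pixel
    y_mm = (yi - n / 2) * pixel
    factor = 1.0 - 1.0 / 0.9
    disp = np.stack([factor * x_mm, factor * y_mm], axis=-1)
    r = np.hypot(x_mm, y_mm)
    mask = (r > 10) & (r < 22)
    ecc = compute_ecc(disp, mask, (n / 2, n / 2), pixel)
    mid = mask & (r > 13) & (r < 19)  # mid-wall, away from mask edges
    assert np.nanmean(ecc[mid]) == pytest.approx(-0.095, abs=0.01)


def test_end_to_end_strain_on_analytic_displacement():
    # finite-difference Green-Lagrange on the exact Eulerian field matches
    # the closed-form E_cc inside an eroded wall
    from scipy.ndimage import binary_erosion

    cfg = PhantomConfig(grid_size=48, n_coils=1, n_phases=6)
    truth = render_dense_images(cfg)
    n = cfg.grid_size
    errs = []
    for f in range(cfg.n_phases):
        ecc = compute_ecc(
            truth.eulerian_displacement_mm[f],
            truth.myocardial_mask[f],
            (n / 2, n / 2),
            cfg.pixel_mm,
        )
        sel = binary_erosion(truth.myocardial_mask[f], iterations=2)
        if sel.any():
            errs.append(ecc[sel] - truth.ecc_map[f][sel])
    err = np.concatenate(errs)
    assert np.sqrt(np.mean(err**2)) < 0.01


def test_segment_stats_uniform_and_permutation():
    n = 32
    xi, yi = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(xi - n / 2, yi - n / 2)
    mask = ((r > 5) & (r < 12))[None]
    ecc = np.where(mask, -0.1, np.nan)
    res = segment_stats(ecc, mask, (n / 2, n / 2))
    assert np.allclose(res.segment_means, -0.1)
    assert np.allclose(res.segment_sds, 0.0)
    assert res.segment_labels == tuple(AHA_MID_SEGMENTS)
    # a 60-degree rotation of the angular reference permutes segments
    theta = np.arctan2(yi - n / 2, xi - n / 2)
    ecc_var = np.where(mask[0], np.cos(theta), np.nan)[None]
    base = segment_stats(ecc_var, mask, (n / 2, n / 2))
    rot = segment_stats(
        ecc_var, mask, (n / 2, n / 2), rv_insertion_angle_rad=np.pi / 3
    )
    assert np.allclose(rot.segment_means[:, 0], np.roll(base.segment_means[:, 0], -1),
                       atol=1e-12)


def test_segment_stats_empty_segment_is_nan():
    n = 32
    mask = np.zeros((1, n, n), dtype=bool)
    mask[0, n // 2 + 6, n // 2] = True  # single pixel: most segments empty
    ecc = np.where(mask, -0.2, np.nan)
    res = segment_stats(ecc, mask, (n / 2, n / 2))
    assert np.isnan(res.segment_means).sum() == 5
    assert np.nansum(res.segment_means) == pytest.approx(-0.2)


def test_analyze_strain_dataframe(small_run):
    _, result = small_run
    df = result.strain_noisy.to_dataframe()
    assert set(df.columns) == {"segment", "frame", "ecc_mean", "ecc_sd"}
    nph = result.strain_noisy.segment_means.shape[1]
    assert len(df) == 6 * nph
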