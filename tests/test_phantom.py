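"""Phantom motion model, analytic strain oracle and DENSE signal rendering."""

import numpy as np
import pytest

from spiraldense.phantom import (
    PhantomConfig,
    analytic_ecc,
    bulk_translation,
    contraction_course,
    deform_points,
    deformed_mask,
    eulerian_displacement,
    make_motion_field,
    render_dense_images,
    twist_rad,
)


def _static(**kw) -> PhantomConfig:
    base = dict(
        grid_size=32,
        n_coils=1,
        n_phases=21,
        systole_fraction=0.35,
        peak_contraction_fraction=0.0,
        peak_twist_deg=0.0,
        bulk_translation_mm=(0.0, 0.0),
    )
    base.update(kw)
    return PhantomConfig(**base)


PEAK_FRAME = 7  # t = 7/20 = systole_fraction -> course shape exactly 1


def test_identity_motion_zero_displacement():
    cfg = _static()
    for f in range(cfg.n_phases):
        disp, _ = make_motion_field(cfg, f)
        assert np.allclose(disp, 0.0, atol=1e-12)


def test_course_shape_peaks_at_systole():
    cfg = _static(peak_contraction_fraction=0.1)
    courses = [contraction_course(cfg, f) for f in range(cfg.n_phases)]
    assert courses[0] == 0.0
    assert courses[PEAK_FRAME] == pytest.approx(0.1)
    assert max(courses) == courses[PEAK_FRAME]
    # cine ends at the residual deformation, not back at zero
    assert courses[-1] == pytest.approx(0.1 * cfg.end_diastolic_residual)


def test_rigid_rotation_chord_length():
    # twist 6 degrees at R = 30 mm -> chord 2 * 30 * sin(3 deg)
    cfg = _static(peak_twist_deg=6.0)
    assert twist_rad(cfg, PEAK_FRAME) == pytest.approx(np.deg2rad(6.0))
    point = np.array([30.0, 0.0])
    moved = deform_points(cfg, PEAK_FRAME, point)
    chord = np.linalg.norm(moved - point)
    assert chord == pytest.approx(2 * 30 * np.sin(np.deg2rad(3.0)), rel=1e-9)


def test_pure_contraction_radial_displacement():
    # c = 0.1, w = 1 at R = 30 -> radial displacement -3.0 mm
    cfg = _static(peak_contraction_fraction=0.1, transmural_falloff=0.0)
    moved = deform_points(cfg, PEAK_FRAME, np.array([30.0, 0.0]))
    assert moved == pytest.approx([27.0, 0.0])


def test_bulk_translation_is_rigid():
    cfg = _static(bulk_translation_mm=(2.0, -1.0))
    b = bulk_translation(cfg, PEAK_FRAME)
    assert b == pytest.approx([2.0, -1.0])
    pts = np.array([[10.0, 5.0], [-8.0, 3.0]])
    moved = deform_points(cfg, PEAK_FRAME, pts)
    assert np.allclose(moved, pts + b)
    # rigid motion: exactly zero analytic strain
    ecc = analytic_ecc(cfg, PEAK_FRAME)[deformed_mask(cfg, PEAK_FRAME)]
    assert np.max(np.abs(ecc)) < 1e-12


def test_analytic_ecc_uniform_contraction():
    # lambda = 0.9 -> E_cc = (0.81 - 1) / 2 = -0.095
    cfg = _static(peak_contraction_fraction=0.1, transmural_falloff=0.0)
    mask = deformed_mask(cfg, PEAK_FRAME)
    ecc = analytic_ecc(cfg, PEAK_FRAME)[mask]
    assert np.allclose(ecc, -0.095, atol=1e-4)
    # lambda = 1 (frame 0) -> zero strain
    mask0 = deformed_mask(cfg, 0)
    assert np.allclose(analytic_ecc(cfg, 0)[mask0], 0.0, atol=1e-12)


def test_rigid_rotation_zero_strain():
    cfg = _static(peak_twist_deg=8.0)
    mask = deformed_mask(cfg, PEAK_FRAME)
    assert np.max(np.abs(analytic_ecc(cfg, PEAK_FRAME)[mask])) < 1e-12


def test_eulerian_displacement_consistent_with_lagrangian():
    cfg = PhantomConfig(grid_size=48, n_coils=1, n_phases=6)
    f = 2
    u = eulerian_displacement(cfg, f)
    xx, yy = cfg.pixel_coords()
    cur = np.stack([xx, yy], axis=-1)
    ref = cur - u
    # mapping the recovered reference positions forward returns the pixel
    forward = deform_points(cfg, f, ref)
    mask = deformed_mask(cfg, f)
    err = np.linalg.norm(forward - cur, axis=-1)[mask]
    assert np.max(err) < 1e-3  # interp tabulation tolerance


def test_render_zero_motion_zero_artifact_phase():
    cfg = _static(artifact_amplitude=0.0, n_phases=4)
    truth = render_dense_images(cfg)
    imgs = truth.reference_images
    rel = imgs[:, :, 0, :, 0, 1] * np.conj(imgs[:, :, 0, :, 0, 0])
    sel = np.abs(rel) > 1e-3
    assert np.allclose(np.angle(rel[sel]), 0.0, atol=1e-10)


def test_render_translation_encodes_pi_phase():
    # uniform x-translation of 5 mm at ke = 0.10 -> encoded phase pi (wraps)
    cfg = _static(bulk_translation_mm=(5.0, 0.0), artifact_amplitude=0.0)
    truth = render_dense_images(cfg)
    f = PEAK_FRAME
    imgs = truth.reference_images
    rel = imgs[:, :, 0, f, 0, 1] * np.conj(imgs[:, :, 0, f, 0, 0])
    mask = truth.myocardial_mask[f] & (np.abs(rel) > 1e-3)
    assert np.allclose(np.abs(np.angle(rel[mask])), np.pi, atol=1e-6)


def test_render_phase_cycling_flips_ste_only():
    cfg = _static(artifact_amplitude=0.3, n_phases=4)
    truth = render_dense_images(cfg)
    imgs = truth.reference_images
    # cycle combination (I0 - I1)/2 equals the pure stimulated echo
    combined = (imgs[:, :, 0, :, 0, :] - imgs[:, :, 0, :, 1, :]) / 2
    no_art = render_dense_images(_static(artifact_amplitude=0.0, n_phases=4))
    ste = no_art.reference_images[:, :, 0, :, 0, :]
    assert np.allclose(combined, ste, atol=1e-12)
    # with the artifact present, a single cycle differs from the pure STE
    assert not np.allclose(imgs[:, :, 0, :, 0, :], ste, atol=1e-3)


def test_ground_truth_shapes_and_mask(small_phantom, small_truth):
    ph = small_phantom
    n = ph.grid_size
    t = small_truth
    assert t.reference_images.shape == (
        n, n, ph.n_coils, ph.n_phases, ph.n_phase_cycles, ph.n_encodings
    )
    assert t.displacement_mm.shape == (ph.n_phases, n, n, 2)
    assert t.ecc_map.shape == (ph.n_phases, n, n)
    assert t.myocardial_mask.dtype == bool
    assert t.myocardial_mask.any(axis=(1, 2)).all()  # non-empty every frame
    # systolic circumferential strain is negative (shortening)
    peak = int(np.argmax([contraction_course(ph, f) for f in range(ph.n_phases)]))
    assert np.nanmean(t.ecc_map[peak][t.myocardial_mask[peak]]) < -0.05


def test_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(endocardial_radius_mm=40.0, epicardial_radius_mm=32.0)
    with pytest.raises(ValueError):
        PhantomConfig(n_phase_cycles=3)
    with pytest.raises(ValueError):
        PhantomConfig(n_encodings=2)
    with pytest.raises(ValueError):
        PhantomConfig(peak_contraction_fraction=1.5)
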