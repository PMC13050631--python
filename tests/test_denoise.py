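"""Patch extraction, Casorati reshaping and singular-value thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiraldense.bounds import CalibrationKey, RatioTable
from spiraldense.denoise import (
    GROUPINGS,
    PatchSpec,
    denoise_patch,
    denoise_volume,
    extract_patches,
    from_casorati,
    iter_patch_locations,
    patch_coverage,
    to_casorati,
)
from spiraldense.recon import DenseImageSet


def _random_patch(rng, shape=(3, 3, 4, 5, 2, 3)):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def test_patch_count_128():
    spec = PatchSpec(px=3, py=3, stride=1)
    lx, ly = iter_patch_locations((128, 128), spec)
    assert len(lx) * len(ly) == 15876  # 126^2


def test_single_patch_when_stride_equals_size():
    spec = PatchSpec(px=8, py=8, stride=8)
    lx, ly = iter_patch_locations((8, 8), spec)
    assert (lx, ly) == ([0], [0])


def test_patch_location_convention():
    rng = np.random.default_rng(0)
    img = _random_patch(rng, (6, 6, 2, 2, 2, 3))
    spec = PatchSpec(px=3, py=3, stride=1)
    patches, locations = extract_patches(img, spec)
    i = locations.index((2, 1))
    assert np.array_equal(patches[i], img[2:5, 1:4])


def test_patch_larger_than_image_raises():
    with pytest.raises(ValueError):
        iter_patch_locations((4, 4), PatchSpec(px=5, py=5))


def test_casorati_paper_dimensions():
    rng = np.random.default_rng(1)
    # paper conditions: 3x3 patch, 24 coils, 20 phases, 2 cycles, 3 encodings
    patch = _random_patch(rng, (3, 3, 24, 20, 2, 3))
    mat = to_casorati(patch, PatchSpec(grouping="xych"))
    assert mat.shape == (432, 120)  # (2*3*3*24, 20*2*3)
    mat2 = to_casorati(patch, PatchSpec(grouping="xyph"))
    assert mat2.shape == (360, 144)  # (2*3*3*20, 24*3*2)
    assert np.isrealobj(mat)


def test_casorati_real_patch_zero_imag_block():
    rng = np.random.default_rng(2)
    patch = rng.standard_normal((3, 3, 4, 5, 2, 3)) + 0j
    mat = to_casorati(patch, PatchSpec(grouping="xych"))
    half = mat.shape[0] // 2
    assert np.allclose(mat[half:], 0.0)
    assert np.linalg.norm(mat[:half]) == pytest.approx(
        np.linalg.norm(patch.real), rel=1e-12
    )


@pytest.mark.parametrize("grouping", sorted(GROUPINGS))
@pytest.mark.parametrize("realimag_side", ["spatial", "other"])
def test_casorati_roundtrip_all_groupings(grouping, realimag_side):
    rng = np.random.default_rng(3)
    shape = (3, 3, 4, 5, 2, 3)
    patch = _random_patch(rng, shape)
    spec = PatchSpec(grouping=grouping, realimag_side=realimag_side)
    mat = to_casorati(patch, spec)
    back = from_casorati(mat, shape, spec)
    assert np.array_equal(back, patch)  # exact bijection


def test_casorati_energy_preserved():
    rng = np.random.default_rng(4)
    patch = _random_patch(rng)
    mat = to_casorati(patch, PatchSpec())
    assert np.linalg.norm(mat) == pytest.approx(np.linalg.norm(patch), rel=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    px=st.integers(1, 4),
    py=st.integers(1, 4),
    grouping=st.sampled_from(sorted(GROUPINGS)),
    side=st.sampled_from(["spatial", "other"]),
    seed=st.integers(0, 2**16),
)
def test_casorati_roundtrip_property(px, py, grouping, side, seed):
    rng = np.random.default_rng(seed)
    shape = (px, py, 2, 3, 2, 3)
    patch = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    spec = PatchSpec(px=px, py=py, grouping=grouping, realimag_side=side)
    assert np.array_equal(from_casorati(to_casorati(patch, spec), shape, spec), patch)


def test_denoise_patch_cutoffs():
    rng = np.random.default_rng(5)
    mat = rng.standard_normal((10, 20))
    out, rank = denoise_patch(mat, 0.0)
    assert np.allclose(out, mat, atol=1e-10)  # cutoff 0: identity
    assert rank == 10
    smax = np.linalg.svd(mat, compute_uv=False)[0]
    out2, rank2 = denoise_patch(mat, smax * 1.01)
    assert np.allclose(out2, 0.0) and rank2 == 0
    with pytest.raises(ValueError):
        denoise_patch(mat, -1.0)


def test_patch_spec_validation():
    with pytest.raises(ValueError):
        PatchSpec(px=0)
    with pytest.raises(ValueError):
        PatchSpec(grouping="bogus")
    with pytest.raises(ValueError):
        PatchSpec(realimag_side="left")


def test_patch_coverage_counts():
    cov = patch_coverage((6, 6), PatchSpec(px=3, py=3, stride=1))
    assert cov.min() >= 1
    assert cov[3, 3] == 9  # interior pixel covered by 3x3 = 9 patches
    assert cov[0, 0] == 1  # corner covered once


def _fake_table(key, shape2d, spec):
    lx, ly = iter_patch_locations(shape2d, spec)
    ones = np.ones((len(lx), len(ly)))
    return RatioTable(key=key, r_upper=ones, r_lower=ones, n_mc=10, sigma_cal=1.0)


def _image_set(rng, n=10, dims=(3, 4, 2, 3)):
    data = rng.standard_normal((n, n, *dims)) + 1j * rng.standard_normal(
        (n, n, *dims)
    )
    return DenseImageSet(images=data, pixel_mm=1.0, ke_cyc_per_mm=0.1, whitened=True)


def _key(spec, n=10, dims=(3, 4, 2, 3)):
    return CalibrationKey(
        matrix_size=n,
        dims=dims,
        trajectory="test",
        patch=spec.key_tuple(),
        grouping=spec.grouping,
        realimag_side=spec.realimag_side,
        whitened=True,
    )


def test_denoise_volume_cutoff_zero_is_identity():
    rng = np.random.default_rng(6)
    spec = PatchSpec()
    imgs = _image_set(rng)
    table = _fake_table(_key(spec), (10, 10), spec)
    out = denoise_volume(imgs, spec, table, fixed_cutoff=0.0)
    assert np.allclose(out.images, imgs.images, atol=1e-10)
    assert out.denoised


def test_denoise_volume_key_mismatch_raises():
    rng = np.random.default_rng(7)
    spec = PatchSpec()
    imgs = _image_set(rng)
    wrong_spec = PatchSpec(grouping="xyph")
    table = _fake_table(_key(wrong_spec), (10, 10), wrong_spec)
    with pytest.raises(KeyError):
        denoise_volume(imgs, spec, table, key=_key(spec))
    # mismatched data shape against a matching-looking key also refuses
    table2 = _fake_table(_key(spec, n=12), (12, 12), spec)
    with pytest.raises(KeyError):
        denoise_volume(imgs, spec, table2)


def test_denoise_volume_reduces_noise_on_lowrank_signal():
    rng = np.random.default_rng(8)
    n, dims = 12, (3, 4, 2, 3)
    base = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    signal = np.broadcast_to(base[..., None, None, None, None], (n, n, *dims)).copy()
    noise = 0.3 * (
        rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
    )
    imgs = DenseImageSet(
        images=signal + noise, pixel_mm=1.0, ke_cyc_per_mm=0.1, whitened=True
    )
    spec = PatchSpec()
    table = _fake_table(_key(spec, n=n), (n, n), spec)
    out = denoise_volume(imgs, spec, table)
    err_before = np.linalg.norm(imgs.images - signal)
    err_after = np.linalg.norm(out.images - signal)
    assert err_after < 0.5 * err_before
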