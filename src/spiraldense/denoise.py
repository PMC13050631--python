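"""Patch extraction, Casorati-like reshaping and singular-value thresholding.

Overlapping 6D patches (px, py, Nch, Nph, Npc, Nenc) slide over the two
spatial dimensions only. Each patch is reshaped into a real-valued 2D
Casorati-like matrix under a dimension-grouping strategy that always keeps
(x, y) together on one side, joined by one of {coil, phase, cycle, encoding};
the real and imaginary parts are concatenated along the side holding the
spatial dimensions (configurable). Singular values at or below the calibrated
noise cutoff are zeroed and the overlapping denoised patches are averaged
back into the 6D volume with uniform weights.

Axis ordering inside each Casorati side is fixed: within the spatial side the
order is (real/imag block, x, y, grouped dim); within the other side the
remaining dims keep their (ch, ph, pc, enc) array order. Any fixed bijection
is valid -- what matters is that calibration and denoising share it, which the
CalibrationKey hash enforces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bounds import CalibrationKey, RatioTable, threshold_chain
from .recon import DenseImageSet

#: grouping name -> axis (in (px, py, ch, ph, pc, enc) patch order) that joins
#: the spatial side
GROUPINGS = {"xych": 2, "xyph": 3, "xypc": 4, "xyenc": 5}


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry + dimension grouping strategy."""

    px: int = 3
    py: int = 3
    stride: int = 1
    grouping: str = "xych"
    realimag_side: str = "spatial"  # or "other"

    def __post_init__(self) -> None:
        if self.px < 1 or self.py < 1 or self.stride < 1:
            raise ValueError("px, py, stride must be >= 1")
        if self.grouping not in GROUPINGS:
            raise ValueError(f"grouping must be one of {sorted(GROUPINGS)}")
        if self.realimag_side not in ("spatial", "other"):
            raise ValueError("realimag_side must be 'spatial' or 'other'")

    def key_tuple(self) -> tuple:
        return (self.px, self.py, self.stride)


def iter_patch_locations(
    shape2d: tuple[int, int], spec: PatchSpec
) -> tuple[list[int], list[int]]:
    """Interior-only top-left patch corners along x and y."""
    nx, ny = shape2d
    if spec.px > nx or spec.py > ny:
        raise ValueError("patch larger than image")
    return (
        list(range(0, nx - spec.px + 1, spec.stride)),
        list(range(0, ny - spec.py + 1, spec.stride)),
    )


def _casorati_shape(
    patch_shape: tuple, spec: PatchSpec
) -> tuple[int, int]:
    px, py = patch_shape[0], patch_shape[1]
    d_axis = GROUPINGS[spec.grouping]
    nd = patch_shape[d_axis]
    rest = int(np.prod([patch_shape[ax] for ax in (2, 3, 4, 5) if ax != d_axis]))
    p, q = px * py * nd, rest
    if spec.realimag_side == "spatial":
        return 2 * p, q
    return p, 2 * q


def to_casorati(patch: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Reshape one complex 6D patch into its real Casorati-like matrix."""
    return _casorati_batch(patch[None], spec)[0]


def from_casorati(mat: np.ndarray, patch_shape: tuple, spec: PatchSpec) -> np.ndarray:
    """Exact inverse of :func:`to_casorati`."""
    return _patches_from_casorati(mat[None], patch_shape, spec)[0]


def _casorati_batch(patches: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """(B, px, py, ch, ph, pc, enc) complex -> (B, p, q) real."""
    d_axis = GROUPINGS[spec.grouping] + 1  # +1 for batch axis
    arr = np.moveaxis(patches, d_axis, 3)  # (B, px, py, d, rest...)
    b = arr.shape[0]
    p = arr.shape[1] * arr.shape[2] * arr.shape[3]
    arr = arr.reshape(b, p, -1)
    if spec.realimag_side == "spatial":
        return np.concatenate([arr.real, arr.imag], axis=1)
    return np.concatenate([arr.real, arr.imag], axis=2)


def _patches_from_casorati(
    mats: np.ndarray, patch_shape: tuple, spec: PatchSpec
) -> np.ndarray:
    """(B, p, q) real -> (B, px, py, ch, ph, pc, enc) complex."""
    d_axis = GROUPINGS[spec.grouping]
    nd = patch_shape[d_axis]
    px, py = patch_shape[0], patch_shape[1]
    if spec.realimag_side == "spatial":
        half = mats.shape[1] // 2
        cplx = mats[:, :half, :] + 1j * mats[:, half:, :]
    else:
        half = mats.shape[2] // 2
        cplx = mats[:, :, :half] + 1j * mats[:, :, half:]
    rest_shape = [patch_shape[ax] for ax in (2, 3, 4, 5) if ax != d_axis]
    arr = cplx.reshape(mats.shape[0], px, py, nd, *rest_shape)
    return np.moveaxis(arr, 3, d_axis + 1)


def extract_patches(
    images: np.ndarray, spec: PatchSpec
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """All overlapping 6D patches + their top-left (x, y) locations.

    Materialises every patch; use :func:`casorati_stack` for large volumes.
    """
    locs_x, locs_y = iter_patch_locations(images.shape[:2], spec)
    view = sliding_window_view(images, (spec.px, spec.py), axis=(0, 1))
    sel = view[np.ix_(locs_x, locs_y)]  # (nx, ny, ch, ph, pc, enc, px, py)
    sel = np.moveaxis(sel, (-2, -1), (2, 3))  # (nx, ny, px, py, ch, ph, pc, enc)
    patches = sel.reshape(len(locs_x) * len(locs_y), *sel.shape[2:])
    locations = [(x, y) for x in locs_x for y in locs_y]
    return patches, locations


def casorati_stack(
    images: np.ndarray, spec: PatchSpec
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (x0, mats) per row of patch locations; mats is (n_y, p, q) real.

    Row-wise chunking keeps peak memory bounded for large grids.
    """
    locs_x, locs_y = iter_patch_locations(images.shape[:2], spec)
    view = sliding_window_view(images, (spec.px, spec.py), axis=(0, 1))
    for x0 in locs_x:
        row = view[x0, locs_y]  # (n_y, ch, ph, pc, enc, px, py)
        row = np.moveaxis(row, (-2, -1), (1, 2))  # (n_y, px, py, ch, ph, pc, enc)
        yield x0, _casorati_batch(np.ascontiguousarray(row), spec)


def denoise_patch(casorati: np.ndarray, cutoff_s: float) -> tuple[np.ndarray, int]:
    """Hard singular-value thresholding of one Casorati matrix.

    Singular values s <= cutoff_s are zeroed, the rest kept unchanged.
    Returns the reassembled matrix and the retained rank.
    """
    if cutoff_s < 0:
        raise ValueError("cutoff must be >= 0")
    try:
        u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    except np.linalg.LinAlgError as err:  # pragma: no cover - rare
        raise np.linalg.LinAlgError(f"SVD did not converge: {err}") from err
    keep = s > cutoff_s
    return (u[:, keep] * s[keep]) @ vt[keep], int(np.count_nonzero(keep))


def patch_coverage(shape2d: tuple[int, int], spec: PatchSpec) -> np.ndarray:
    """Number of patches covering each pixel (>= 1 for stride 1, px <= Nx)."""
    locs_x, locs_y = iter_patch_locations(shape2d, spec)
    cov = np.zeros(shape2d)
    wx = np.zeros(shape2d[0])
    wy = np.zeros(shape2d[1])
    for x in locs_x:
        wx[x : x + spec.px] += 1
    for y in locs_y:
        wy[y : y + spec.py] += 1
    cov[:] = wx[:, None] * wy[None, :]
    return cov


def denoise_volume(
    images: DenseImageSet,
    spec: PatchSpec,
    table: RatioTable,
    key: CalibrationKey | None = None,
    fixed_cutoff: float | None = None,
) -> DenseImageSet:
    """Denoise the full 6D image set patch-by-patch with overlap averaging.

    Each patch's singular-value cutoff comes from the calibrated ratio chain
    applied to the patch's own smallest Gram eigenvalue; pass ``fixed_cutoff``
    to bypass calibration (0 reproduces the input exactly, which isolates the
    overlap-averaging bookkeeping).
    """
    data = images.images
    nx, ny = data.shape[:2]
    if fixed_cutoff is None:
        if key is not None and key != table.key:
            raise KeyError(
                f"calibration key mismatch: data={key} vs table={table.key}"
            )
        tk = table.key
        if (
            tk.matrix_size != nx
            or tuple(tk.dims) != data.shape[2:]
            or tk.patch != spec.key_tuple()
            or tk.grouping != spec.grouping
            or tk.realimag_side != spec.realimag_side
        ):
            raise KeyError(
                "calibration table does not match data/patch configuration: "
                f"table key {tk}, data shape {data.shape}, patch {spec}"
            )
    locs_x, locs_y = iter_patch_locations((nx, ny), spec)
    out = np.zeros_like(data)
    cov = patch_coverage((nx, ny), spec)
    if np.min(cov) < 1:
        raise ValueError("stride leaves uncovered pixels")
    patch_shape = (spec.px, spec.py, *data.shape[2:])
    for row_idx, (x0, mats) in enumerate(casorati_stack(data, spec)):
        u, s, vt = np.linalg.svd(mats, full_matrices=False)
        if fixed_cutoff is not None:
            cutoffs = np.full(mats.shape[0], float(fixed_cutoff))
        else:
            p, q = mats.shape[1], mats.shape[2]
            qn, gamma = max(p, q), min(p, q) / max(p, q)
            a_b_hat = s[:, -1] ** 2 / qn
            _, cutoffs = threshold_chain(
                a_b_hat, gamma, qn, table.r_upper[row_idx], table.r_lower[row_idx]
            )
        s_thr = np.where(s > cutoffs[:, None], s, 0.0)
        den = np.einsum("bik,bk,bkj->bij", u, s_thr, vt)
        patches = _patches_from_casorati(den, patch_shape, spec)
        for j, y0 in enumerate(locs_y):
            out[x0 : x0 + spec.px, y0 : y0 + spec.py] += patches[j]
    out /= cov[:, :, None, None, None, None]
    return DenseImageSet(
        images=out,
        pixel_mm=images.pixel_mm,
        ke_cyc_per_mm=images.ke_cyc_per_mm,
        whitened=images.whitened,
        denoised=True,
    )
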