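"""Phase-cycle/coil combination, phase unwrapping, displacement and E_cc.

Displacement interpretation: the encoded phase at a pixel is the displacement
of the tissue *currently* at that pixel relative to its reference
(end-diastolic) position -- an Eulerian sampling of a Lagrangian quantity.
The reference position of each pixel is X = x - u(x); the deformation
gradient follows from F^-1 = dX/dx = I - du/dx, and the Green-Lagrange
tensor E = (F^T F - I)/2 is projected onto the circumferential unit vector
at the reference position about the LV center:

    E_cc = e_theta(X)^T . E . e_theta(X).

Spatial derivatives use Gaussian-smoothed central differences with
mask-normalised convolution so that pixels outside the myocardium do not
contaminate the wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap2d

from .recon import DenseImageSet

#: AHA mid-ventricular short-axis segment names, counter-clockwise starting
#: at the anterior RV insertion.
AHA_MID_SEGMENTS = [
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
]


@dataclass
class CombinedImages:
    """Cycle- and coil-combined complex images (Nx, Ny, Nph, Nenc)."""

    images: np.ndarray
    pixel_mm: float
    ke_cyc_per_mm: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.images)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.images)


@dataclass
class StrainResult:
    """Segmental circumferential strain summary + pixelwise maps."""

    displacement_mm: np.ndarray  # (Nph, Nx, Ny, 2)
    ecc_maps: np.ndarray  # (Nph, Nx, Ny), NaN outside mask
    masks: np.ndarray  # (Nph, Nx, Ny) bool
    segment_means: np.ndarray  # (6, Nph)
    segment_sds: np.ndarray  # (6, Nph)
    segment_labels: tuple = tuple(AHA_MID_SEGMENTS)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, label in enumerate(self.segment_labels):
            for f in range(self.segment_means.shape[1]):
                rows.append(
                    {
                        "segment": label,
                        "frame": f,
                        "ecc_mean": self.segment_means[s, f],
                        "ecc_sd": self.segment_sds[s, f],
                    }
                )
        return pd.DataFrame(rows)


def combine_phase_cycles(images: DenseImageSet) -> np.ndarray:
    """Collapse the phase-cycling dimension: (I_cycle0 - I_cycle1) / 2.

    The stimulated echo flips sign between the two cycles while the artifact
    echo does not, so the complex difference cancels the artifact exactly in
    the noise-free case. Returns (Nx, Ny, Nch, Nph, Nenc).
    """
    data = images.images
    npc = data.shape[4]
    if npc == 1:
        return data[:, :, :, :, 0, :]
    if npc != 2:
        raise ValueError("only 1 or 2 phase cycles supported")
    return (data[:, :, :, :, 0, :] - data[:, :, :, :, 1, :]) / 2.0


def coil_combine(
    images: np.ndarray,
    sensitivities: np.ndarray,
    pixel_mm: float,
    ke_cyc_per_mm: float,
) -> CombinedImages:
    """Phase-preserving sensitivity-weighted coil combination.

    combined = sum_c conj(S_c) I_c / sum_c |S_c|^2. ``images`` is
    (Nx, Ny, Nch, Nph, Nenc); ``sensitivities`` (Nx, Ny, Nch) must be in the
    same coil basis as the images (i.e. whitened if the images are).
    """
    sos = np.sum(np.abs(sensitivities) ** 2, axis=-1)
    if np.min(sos) <= 0:
        raise ValueError("zero sensitivity norm inside the field of view")
    num = np.einsum("xyc,xycpe->xype", sensitivities.conj(), images)
    return CombinedImages(
        images=num / sos[:, :, None, None],
        pixel_mm=pixel_mm,
        ke_cyc_per_mm=ke_cyc_per_mm,
    )


def _unwrap_frame(phase: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """2D unwrapping inside the mask; zero outside."""
    if mask.sum() == 0:
        return np.zeros_like(phase)
    marr = np.ma.array(phase, mask=~mask)
    out = np.asarray(_unwrap2d(marr))
    out = np.where(mask, out, 0.0)
    return out


def unwrap_phase(
    phase: np.ndarray, masks: np.ndarray, temporal_seed_frame: int = 0
) -> np.ndarray:
    """Unwrap (Nx, Ny, Nph) phase maps spatially, then enforce temporal
    consistency of the global 2*pi offset, seeded at ``temporal_seed_frame``
    where displacement (hence phase) is near zero.

    The output differs from the wrapped input by integer multiples of 2*pi at
    every masked pixel.
    """
    nph = phase.shape[2]
    out = np.zeros_like(phase)
    for f in range(nph):
        out[:, :, f] = _unwrap_frame(phase[:, :, f], masks[f])
    # seed: remove whole-image 2*pi offset at the seed frame
    seed_mask = masks[temporal_seed_frame]
    if seed_mask.any():
        med = np.median(out[:, :, temporal_seed_frame][seed_mask])
        out[:, :, temporal_seed_frame] -= 2 * np.pi * np.round(med / (2 * np.pi))
    # propagate forward and backward from the seed
    order = list(range(temporal_seed_frame + 1, nph)) + list(
        range(temporal_seed_frame - 1, -1, -1)
    )
    for f in order:
        prev = f - 1 if f > temporal_seed_frame else f + 1
        both = masks[f] & masks[prev]
        if not both.any():
            continue
        diff = np.median(out[:, :, f][both] - out[:, :, prev][both])
        out[:, :, f] -= 2 * np.pi * np.round(diff / (2 * np.pi))
    return out


def phase_to_displacement(unwrapped: np.ndarray, ke_cyc_per_mm: float) -> np.ndarray:
    """u = delta_phi / (2 pi ke), in mm."""
    if ke_cyc_per_mm <= 0:
        raise ValueError("encoding frequency must be positive")
    return unwrapped / (2 * np.pi * ke_cyc_per_mm)


def displacement_from_combined(
    combined: CombinedImages, masks: np.ndarray
) -> np.ndarray:
    """Encoded displacement field (Nph, Nx, Ny, 2) from combined images.

    The x/y-encoded images are referenced to the phase-reference encoding
    (index 0) before unwrapping, which removes the static background phase.
    """
    imgs = combined.images
    nph = imgs.shape[2]
    disp = np.zeros((nph, imgs.shape[0], imgs.shape[1], 2))
    for comp, enc in ((0, 1), (1, 2)):
        rel = imgs[:, :, :, enc] * np.conj(imgs[:, :, :, 0])
        unwrapped = unwrap_phase(np.angle(rel), masks)
        disp[..., comp] = np.moveaxis(
            phase_to_displacement(unwrapped, combined.ke_cyc_per_mm), 2, 0
        )
    return disp


def _masked_smooth(field: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with mask-normalised convolution."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(field * m, sigma)
    den = ndimage.gaussian_filter(m, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 1e-6, num / den, 0.0)


def compute_ecc(
    displacement: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float],
    pixel_mm: float,
    smoothing_px: float = 1.0,
) -> np.ndarray:
    """Green-Lagrange circumferential strain map for one frame.

    ``displacement`` is (Nx, Ny, 2) in mm on the current (Eulerian) grid;
    ``center`` is the LV center in pixel coordinates. Returns E_cc with NaN
    outside the mask.
    """
    n = displacement.shape[0]
    if not (0 <= center[0] < n and 0 <= center[1] < displacement.shape[1]):
        raise ValueError("center outside image")
    thickness = mask.any(axis=1).sum()
    if 0 < thickness < 2:
        smoothing_px = max(smoothing_px, 2.0)
    ux = _masked_smooth(displacement[..., 0], mask, smoothing_px)
    uy = _masked_smooth(displacement[..., 1], mask, smoothing_px)
    dux_dx, dux_dy = np.gradient(ux, pixel_mm)
    duy_dx, duy_dy = np.gradient(uy, pixel_mm)
    # F^-1 = I - du/dx, pixelwise 2x2 inverse
    a11, a12 = 1.0 - dux_dx, -dux_dy
    a21, a22 = -duy_dx, 1.0 - duy_dy
    det = a11 * a22 - a12 * a21
    det = np.where(np.abs(det) < 1e-9, 1e-9, det)
    f11, f12 = a22 / det, -a12 / det
    f21, f22 = -a21 / det, a11 / det
    # E = (F^T F - I) / 2
    e11 = 0.5 * (f11 * f11 + f21 * f21 - 1.0)
    e22 = 0.5 * (f12 * f12 + f22 * f22 - 1.0)
    e12 = 0.5 * (f11 * f12 + f21 * f22)
    # circumferential direction at the reference position X = x - u
    xi, yi = np.meshgrid(np.arange(n), np.arange(displacement.shape[1]), indexing="ij")
    x_mm = (xi - center[0]) * pixel_mm - ux
    y_mm = (yi - center[1]) * pixel_mm - uy
    theta = np.arctan2(y_mm, x_mm)
    ct, st = -np.sin(theta), np.cos(theta)
    ecc = e11 * ct**2 + 2 * e12 * ct * st + e22 * st**2
    return np.where(mask, ecc, np.nan)


def segment_labels_map(
    shape2d: tuple[int, int],
    center: tuple[float, float],
    rv_insertion_angle_rad: float = 0.0,
) -> np.ndarray:
    """Pixelwise AHA mid-level segment index (0-5), 60 deg sectors CCW from
    the anterior RV insertion angle."""
    xi, yi = np.meshgrid(np.arange(shape2d[0]), np.arange(shape2d[1]), indexing="ij")
    theta = np.arctan2(yi - center[1], xi - center[0])
    rel = np.mod(theta - rv_insertion_angle_rad, 2 * np.pi)
    return np.floor(rel / (np.pi / 3)).astype(int) % 6


def segment_stats(
    ecc_maps: np.ndarray,
    masks: np.ndarray,
    center: tuple[float, float],
    displacement: np.ndarray | None = None,
    rv_insertion_angle_rad: float = 0.0,
) -> StrainResult:
    """Per-segment, per-frame mean and SD of E_cc over masked pixels.

    Empty segments yield NaN (flagged missing, not zero).
    """
    nph = ecc_maps.shape[0]
    seg = segment_labels_map(ecc_maps.shape[1:], center, rv_insertion_angle_rad)
    means = np.full((6, nph), np.nan)
    sds = np.full((6, nph), np.nan)
    for f in range(nph):
        valid = masks[f] & np.isfinite(ecc_maps[f])
        for s in range(6):
            vals = ecc_maps[f][valid & (seg == s)]
            if vals.size:
                means[s, f] = vals.mean()
                sds[s, f] = vals.std(ddof=1) if vals.size > 1 else 0.0
    if displacement is None:
        displacement = np.zeros((nph, *ecc_maps.shape[1:], 2))
    return StrainResult(
        displacement_mm=displacement,
        ecc_maps=ecc_maps,
        masks=masks,
        segment_means=means,
        segment_sds=sds,
    )


def analyze_strain(
    combined: CombinedImages,
    masks: np.ndarray,
    center: tuple[float, float] | None = None,
    smoothing_px: float = 1.0,
    rv_insertion_angle_rad: float = 0.0,
) -> StrainResult:
    """Full strain chain: displacement -> E_cc maps -> segment statistics."""
    n = combined.images.shape[0]
    if center is None:
        center = (n / 2, combined.images.shape[1] / 2)
    disp = displacement_from_combined(combined, masks)
    nph = disp.shape[0]
    ecc = np.full((nph, n, combined.images.shape[1]), np.nan)
    for f in range(nph):
        ecc[f] = compute_ecc(
            disp[f], masks[f], center, combined.pixel_mm, smoothing_px
        )
    return segment_stats(
        ecc, masks, center, displacement=disp,
        rv_insertion_angle_rad=rv_insertion_angle_rad,
    )
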