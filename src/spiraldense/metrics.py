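"""Quantitative evaluation metrics and comparison statistics.

Apparent SNR, phase SNR and scan efficiency follow the standard DENSE
definitions; NRMSE is computed against a noise-free reference; the normalized
image gradient quantifies edge sharpness; Bland-Altman and the Wilcoxon
signed-rank test summarise agreement between paired measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RoiSpec:
    """Myocardium + background regions used by the SNR metrics."""

    myocardium_masks: np.ndarray  # (Nph, Nx, Ny) bool
    background_center: tuple[int, int]
    background_radius: int
    mid_diastolic_frame: int = -1
    end_diastolic_frame: int = 0

    def background_mask(self, shape2d: tuple[int, int]) -> np.ndarray:
        xi, yi = np.meshgrid(
            np.arange(shape2d[0]), np.arange(shape2d[1]), indexing="ij"
        )
        return (xi - self.background_center[0]) ** 2 + (
            yi - self.background_center[1]
        ) ** 2 <= self.background_radius**2


def default_background_roi(
    shape2d: tuple[int, int], object_mask: np.ndarray | None = None
) -> tuple[tuple[int, int], int]:
    """Corner-quadrant circular background ROI, verified disjoint from the
    object support when a mask is given."""
    n = shape2d[0]
    center = (n // 8, n // 8)
    radius = max(2, n // 12)
    if object_mask is not None:
        xi, yi = np.meshgrid(np.arange(n), np.arange(shape2d[1]), indexing="ij")
        circ = (xi - center[0]) ** 2 + (yi - center[1]) ** 2 <= radius**2
        if (circ & object_mask).any():
            raise ValueError("background ROI overlaps the object support")
    return center, radius


def apparent_snr(magnitude: np.ndarray, roi: RoiSpec) -> tuple[np.ndarray, float]:
    """Per-frame mu/sigma and the across-frame mean.

    ``magnitude`` is (Nx, Ny, Nph); mu = mean myocardial magnitude,
    sigma = SD of the background magnitude.
    """
    bg = roi.background_mask(magnitude.shape[:2])
    nph = magnitude.shape[2]
    vals = np.empty(nph)
    for f in range(nph):
        sd = magnitude[:, :, f][bg].std(ddof=1)
        if sd == 0:
            raise ZeroDivisionError("zero background standard deviation")
        vals[f] = magnitude[:, :, f][roi.myocardium_masks[f]].mean() / sd
    return vals, float(vals.mean())


def phase_snr(unwrapped_phase: np.ndarray, roi: RoiSpec) -> float:
    """mean(myocardial phase at mid-diastole) / SD(myocardial phase at
    end-diastole). ``unwrapped_phase`` is (Nx, Ny, Nph)."""
    mid = roi.mid_diastolic_frame % unwrapped_phase.shape[2]
    end = roi.end_diastolic_frame % unwrapped_phase.shape[2]
    num = unwrapped_phase[:, :, mid][roi.myocardium_masks[mid]].mean()
    den = unwrapped_phase[:, :, end][roi.myocardium_masks[end]].std(ddof=1)
    if den == 0:
        raise ZeroDivisionError("zero end-diastolic phase SD")
    return float(num / den)


def scan_efficiency(
    apparent_snr_value: float, n_heartbeats: float, voxel_mm3: float
) -> float:
    """Apparent SNR per heartbeat of acquisition per mm^3 of voxel volume."""
    if apparent_snr_value <= 0 or n_heartbeats <= 0 or voxel_mm3 <= 0:
        raise ValueError("inputs must be positive")
    return apparent_snr_value / (n_heartbeats * voxel_mm3)


def nrmse(images: np.ndarray, reference: np.ndarray) -> float:
    """||x - ref||_2 / ||ref||_2 over the full (possibly complex) arrays."""
    if images.shape != reference.shape:
        raise ValueError("shape mismatch")
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0:
        raise ZeroDivisionError("zero reference norm")
    return float(np.linalg.norm(images - reference) / ref_norm)


def normalized_gradient(
    myocardial_intensity: float, background_intensity: float, d_points: float
) -> float:
    """Edge sharpness (Im - Ia) / (Im * d); larger = sharper."""
    if myocardial_intensity <= 0:
        raise ValueError("myocardial intensity must be positive")
    return (myocardial_intensity - background_intensity) / (
        myocardial_intensity * d_points
    )


def profile_normalized_gradient(
    magnitude: np.ndarray,
    start: tuple[float, float],
    stop: tuple[float, float],
    n_samples: int = 50,
) -> float:
    """Normalized gradient along a profile crossing the epicardial border.

    Im is the maximum profile intensity (myocardium), Ia the minimum beyond it
    (background); d is their separation in profile samples.
    """
    from scipy.ndimage import map_coordinates

    t = np.linspace(0, 1, n_samples)
    coords = np.stack(
        [
            start[0] + t * (stop[0] - start[0]),
            start[1] + t * (stop[1] - start[1]),
        ]
    )
    prof = map_coordinates(magnitude.astype(float), coords, order=1)
    i_m = int(np.argmax(prof))
    if i_m == n_samples - 1:
        raise ValueError("profile does not cross the border")
    i_a = i_m + 1 + int(np.argmin(prof[i_m + 1 :]))
    return normalized_gradient(prof[i_m], prof[i_a], float(i_a - i_m))


def bland_altman(x_values: np.ndarray, y_values: np.ndarray):
    """Mean difference and 1.96-SD limits of agreement of d = x - y."""
    x = np.asarray(x_values, float)
    y = np.asarray(y_values, float)
    d = x - y
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ValueError("need at least 2 paired finite values")
    md = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return md, md - half, md + half


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
):
    """Wilcoxon signed-rank test on paired samples; zero differences dropped.

    Exact null distribution for n <= 25 without ties, normal approximation
    with continuity/tie correction otherwise.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
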