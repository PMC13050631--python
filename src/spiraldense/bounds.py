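"""Marchenko-Pastur noise bounds and Monte-Carlo ratio calibration.

For an i.i.d. Gaussian matrix X (p x q, p <= q, entry variance sigma^2) the
eigenvalues of Y = (1/q) X X^T concentrate on [a, b] with

    a = sigma^2 (1 - sqrt(gamma))^2,   b = sigma^2 (1 + sqrt(gamma))^2,
    gamma = p / q.

Gridding a non-Cartesian acquisition correlates the image-domain noise, so the
empirical bounds a_B, b_B of a Casorati-like noise matrix B = Sigma^{1/2} X
differ from the i.i.d. bounds. The ratios b_B/b and a/a_B depend only on the
aspect ratio and the (trajectory- and patch-dependent) covariance, so the
thresholding chain

    b_B_hat = (b_B/b) * (b/a) * (a/a_B) * a_B_hat

recovers the local noise-eigenvalue ceiling from the *smallest* eigenvalue
a_B_hat of a data patch, once the two unknown ratios have been estimated by
Monte-Carlo simulation of noise-only acquisitions pushed through the same
reconstruction path as the data. The mean over ``n_mc`` noise-only
realisations (default 10), kept per patch location because gridded noise is
non-stationary, is the estimator.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class MPBounds:
    """Closed-form Marchenko-Pastur support for i.i.d. noise."""

    sigma2: float
    gamma: float
    a: float
    b: float


def mp_bounds(sigma2: float, p: int, q: int) -> MPBounds:
    """MP support [a, b] for a p x q matrix with entry variance sigma2."""
    if sigma2 <= 0 or p < 1 or q < 1:
        raise ValueError("need sigma2 > 0 and p, q >= 1")
    gamma = min(p, q) / max(p, q)
    sg = np.sqrt(gamma)
    return MPBounds(
        sigma2=sigma2,
        gamma=gamma,
        a=sigma2 * (1 - sg) ** 2,
        b=sigma2 * (1 + sg) ** 2,
    )


def mp_pdf(lam: np.ndarray, sigma2: float, gamma: float) -> np.ndarray:
    """MP eigenvalue density; zero outside [a, b]."""
    lam = np.asarray(lam, dtype=float)
    sg = np.sqrt(gamma)
    a = sigma2 * (1 - sg) ** 2
    b = sigma2 * (1 + sg) ** 2
    out = np.zeros_like(lam)
    inside = (lam >= a) & (lam <= b) & (lam > 0)
    li = lam[inside]
    out[inside] = np.sqrt((b - li) * (li - a)) / (2 * np.pi * gamma * li * sigma2)
    return out


@dataclass(frozen=True)
class SpectrumResult:
    """Descending eigenvalues of (1/q) B B^T for one Casorati matrix."""

    eigenvalues: np.ndarray
    p: int
    q: int


def eigen_spectrum(matrix: np.ndarray) -> SpectrumResult:
    """Gram-matrix eigenvalues of the smaller dimension, scaled by 1/max(p,q).

    Identical to (singular values)^2 / q with q = max(p, q); orientation is
    normalised so groupings with p > q are handled transparently.
    """
    mat = np.asarray(matrix)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("need a non-empty 2D matrix")
    s = np.linalg.svd(mat, compute_uv=False)
    q = max(mat.shape)
    return SpectrumResult(eigenvalues=s**2 / q, p=min(mat.shape), q=q)


@dataclass(frozen=True)
class CalibrationKey:
    """Everything that must match between calibration and denoising."""

    matrix_size: int
    dims: tuple  # (Nch, Nph, Npc, Nenc)
    trajectory: str
    patch: tuple  # (px, py, stride)
    grouping: str
    realimag_side: str
    whitened: bool

    def hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:16]


@dataclass
class RatioTable:
    """Monte-Carlo-estimated bound ratios per patch location."""

    key: CalibrationKey
    r_upper: np.ndarray  # (n_loc_x, n_loc_y): mean b_B / b
    r_lower: np.ndarray  # (n_loc_x, n_loc_y): mean a / a_B
    n_mc: int
    sigma_cal: float

    def __post_init__(self) -> None:
        if self.n_mc < 2:
            raise ValueError("n_mc must be >= 2")
        for arr in (self.r_upper, self.r_lower):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError("ratio entries must be finite and positive")

    @property
    def mean_r_upper(self) -> float:
        return float(np.mean(self.r_upper))

    @property
    def mean_r_lower(self) -> float:
        return float(np.mean(self.r_lower))


def calibrate_ratios(
    noise_image_fn: Callable[[int], np.ndarray],
    key: CalibrationKey,
    patch_spec,
    n_mc: int = 10,
    sigma_cal: float = 1.0,
    seed: int = 0,
) -> RatioTable:
    """Estimate r_upper = b_B/b and r_lower = a/a_B per patch location.

    Parameters
    ----------
    noise_image_fn : callable(seed) -> (Nx, Ny, Nch, Nph, Npc, Nenc) complex
        Produces one noise-only 6D image realisation through exactly the same
        reconstruction path (whitening, gridding, density compensation) that
        the data to be denoised will take.
    key : CalibrationKey
        Identity of the acquisition/patch configuration; persisted with the
        table and checked at denoising time.
    patch_spec : spiraldense.denoise.PatchSpec
        Patch geometry and dimension grouping (shared code path with
        denoising, which is what makes the ratios transferable).
    """
    from .denoise import casorati_stack, iter_patch_locations  # local: no cycle

    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_mc) % (2**31)
    sum_upper = None
    sum_lower = None
    for rep in range(n_mc):
        img = noise_image_fn(int(child_seeds[rep]))
        # empirical per-real-component noise variance of this realisation
        sigma_eff2 = 0.5 * float(np.mean(np.abs(img) ** 2))
        locs_x, locs_y = iter_patch_locations(img.shape[:2], patch_spec)
        if sum_upper is None:
            sum_upper = np.zeros((len(locs_x), len(locs_y)))
            sum_lower = np.zeros((len(locs_x), len(locs_y)))
        for row, (x0, mats) in enumerate(casorati_stack(img, patch_spec)):
            p, q = mats.shape[1], mats.shape[2]
            bounds = mp_bounds(sigma_eff2, p, q)
            s = np.linalg.svd(mats, compute_uv=False)
            qn = max(p, q)
            lam_max = s[:, 0] ** 2 / qn
            lam_min = s[:, -1] ** 2 / qn
            sum_upper[row] += lam_max / bounds.b
            sum_lower[row] += bounds.a / lam_min
    return RatioTable(
        key=key,
        r_upper=sum_upper / n_mc,
        r_lower=sum_lower / n_mc,
        n_mc=n_mc,
        sigma_cal=sigma_cal,
    )


def threshold_chain(
    a_b_hat: np.ndarray, gamma: float, q: int, r_upper, r_lower
) -> tuple[np.ndarray, np.ndarray]:
    """Noise eigenvalue ceiling and singular-value cutoff from a_B_hat.

    b_B_hat = r_upper * (b/a) * r_lower * a_B_hat with
    b/a = (1 + sqrt(gamma))^2 / (1 - sqrt(gamma))^2; the singular-value cutoff
    is s* = sqrt(q * b_B_hat).
    """
    if gamma >= 1.0:
        raise ValueError(
            "gamma = 1: b/a is undefined; use a non-square dimension grouping"
        )
    sg = np.sqrt(gamma)
    b_over_a = (1 + sg) ** 2 / (1 - sg) ** 2
    b_b_hat = np.asarray(r_upper) * b_over_a * np.asarray(r_lower) * np.asarray(a_b_hat)
    return b_b_hat, np.sqrt(q * b_b_hat)


def threshold_from_data(
    casorati: np.ndarray, r_upper: float, r_lower: float
) -> tuple[float, float]:
    """Eigenvalue ceiling b_B_hat and singular-value cutoff for one data patch."""
    spec = eigen_spectrum(casorati)
    gamma = spec.p / spec.q
    a_b_hat = float(spec.eigenvalues[-1])
    b_b_hat, cutoff = threshold_chain(a_b_hat, gamma, spec.q, r_upper, r_lower)
    return float(b_b_hat), float(cutoff)
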