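"""Pre-whitening and density-compensated adjoint-NUFFT reconstruction.

The reconstruction is the plain (non-iterative) adjoint: density-compensation
weights are applied to the spiral samples and the adjoint gridding NUFFT maps
them onto the Cartesian grid, independently per coil, cardiac phase, phase
cycle and encoding. Pre-whitening decorrelates the coil noise with the inverse
Cholesky factor of the empirical coil covariance so that downstream noise-bound
calibration can assume identity coil covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import GriddingNufft
from .sampling import KSpaceSet, SpiralTrajectory


@dataclass
class DenseImageSet:
    """6D complex image array (Nx, Ny, Nch, Nph, Npc, Nenc) + provenance."""

    images: np.ndarray
    pixel_mm: float
    ke_cyc_per_mm: float
    whitened: bool = False
    denoised: bool = False

    def __post_init__(self) -> None:
        if self.images.ndim != 6 or self.images.shape[0] != self.images.shape[1]:
            raise ValueError("images must be (N, N, Nch, Nph, Npc, Nenc)")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("non-finite image values")

    @property
    def matrix_size(self) -> int:
        return self.images.shape[0]


def estimate_prewhitener(
    noise_samples: np.ndarray, max_condition: float = 1e8
) -> np.ndarray:
    """Whitening transform W = L^-1 from noise-only coil samples.

    ``noise_samples`` is (n_samples, Nch) complex; W satisfies
    W @ Sigma_hat @ W^H = I with Sigma_hat the empirical coil covariance.
    """
    x = np.asarray(noise_samples)
    if x.ndim != 2:
        raise ValueError("noise samples must be (n_samples, Nch)")
    n, nch = x.shape
    if n < 10 * nch:
        raise ValueError(f"need >= 10*Nch={10 * nch} noise samples, got {n}")
    cov = x.conj().T @ x / n
    if np.linalg.cond(cov) > max_condition:
        raise np.linalg.LinAlgError("coil covariance is ill-conditioned")
    chol = np.linalg.cholesky(cov)
    return np.linalg.inv(chol)


def apply_prewhitening(kspace: KSpaceSet, whitener: np.ndarray) -> KSpaceSet:
    """Transform the coil dimension of every sample by W."""
    samples = np.einsum("ij,psj...->psi...", whitener, kspace.samples)
    return KSpaceSet(
        samples=samples,
        trajectory=kspace.trajectory,
        noise_sigma=kspace.noise_sigma,
        whitened=True,
    )


def density_compensation(
    traj: SpiralTrajectory, nufft: GriddingNufft | None = None
) -> np.ndarray:
    """Analytic ramp (|k|) density compensation for the Archimedean spiral.

    The weight is proportional to |k| with a floor at half a k-space grid cell
    shared across interleaves, and is normalised so that a unit delta at the
    image center reconstructs with peak value 1.
    """
    coords = traj.flat_coords()
    w = np.hypot(coords[:, 0], coords[:, 1])
    floor = 0.5 / (traj.fov_mm * traj.n_interleaves)
    w = np.maximum(w, floor)
    if nufft is None:
        nufft = GriddingNufft(coords, traj.matrix_size, traj.fov_mm)
    n = traj.matrix_size
    delta = np.zeros((n, n), dtype=complex)
    delta[n // 2, n // 2] = 1.0
    psf_peak = nufft.adjoint(w * nufft.forward(delta))[n // 2, n // 2].real
    return w / psf_peak


def adjoint_nufft_recon(
    kspace: KSpaceSet,
    weights: np.ndarray | None,
    nufft: GriddingNufft | None = None,
    ke_cyc_per_mm: float = 0.10,
) -> DenseImageSet:
    """Density-compensated adjoint NUFFT of every (ch, ph, pc, enc) slice."""
    traj = kspace.trajectory
    if nufft is None:
        nufft = GriddingNufft(traj.flat_coords(), traj.matrix_size, traj.fov_mm)
    npts, nsp = kspace.samples.shape[:2]
    tail = kspace.samples.shape[2:]
    samp = np.moveaxis(kspace.samples, 1, 0).reshape(nsp * npts, -1)
    if weights is not None:
        samp = samp * weights[:, None]
    img = nufft.adjoint(samp)
    img = img.reshape(traj.matrix_size, traj.matrix_size, *tail)
    return DenseImageSet(
        images=img,
        pixel_mm=traj.fov_mm / traj.matrix_size,
        ke_cyc_per_mm=ke_cyc_per_mm,
        whitened=kspace.whitened,
    )


class CorrectionHooks:
    """Registry of pass-through k-space correction callables.

    Placeholder slots for gradient-delay and off-resonance corrections, which
    real acquisitions need but the simulation does not; hooks run in
    registration order and default to the identity.
    """

    def __init__(self) -> None:
        self._hooks: list = []

    def register(self, fn) -> None:
        self._hooks.append(fn)

    def apply(self, kspace: KSpaceSet) -> KSpaceSet:
        for fn in self._hooks:
            kspace = fn(kspace)
        return kspace
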