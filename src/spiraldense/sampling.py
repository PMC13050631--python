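"""Spiral trajectory design, multicoil forward sampling and noise injection.

The trajectory is a uniform-density Archimedean spiral: interleaf m is
interleaf 0 rotated by 2*pi*m/N_sp, and the number of turns is chosen as
matrix_size / (2 * N_sp) so that the combined interleaves satisfy the radial
Nyquist criterion for the prescribed FOV. Coil noise is complex Gaussian,
i.i.d. across k-space samples / phases / cycles / encodings and correlated
across coils through a Hermitian positive-definite covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import GriddingNufft


@dataclass
class SpiralTrajectory:
    """Multi-interleaf 2D spiral in cycles/mm."""

    coords: np.ndarray  # (n_interleaves, n_points, 2)
    fov_mm: float
    matrix_size: int

    @property
    def n_interleaves(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    @property
    def k_max(self) -> float:
        return self.matrix_size / (2.0 * self.fov_mm)

    def flat_coords(self) -> np.ndarray:
        """(n_interleaves * n_points, 2), interleaf-major C order."""
        return self.coords.reshape(-1, 2)

    def signature(self) -> str:
        """Stable identity string used in calibration keys."""
        c = self.coords
        return (
            f"archimedean:nsp={self.n_interleaves}:npts={self.n_points}:"
            f"fov={self.fov_mm:g}:N={self.matrix_size}:kmax={np.abs(c).max():.6f}"
        )


@dataclass
class CoilModel:
    """Smooth complex coil sensitivities + coil noise covariance."""

    sensitivities: np.ndarray  # (Nx, Ny, Nch)
    noise_cov: np.ndarray  # (Nch, Nch), Hermitian PD
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.noise_cov)
        if not np.allclose(cov, cov.conj().T):
            raise ValueError("noise covariance must be Hermitian")
        if np.min(np.linalg.eigvalsh(cov)) <= 0:
            raise ValueError("noise covariance must be positive definite")
        sos = np.sum(np.abs(self.sensitivities) ** 2, axis=-1)
        if np.min(sos) <= 0:
            raise ValueError("sum-of-squares sensitivity must be positive everywhere")

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[-1]


@dataclass
class KSpaceSet:
    """Sampled multicoil k-space: (Npts, N_sp, Nch, Nph, Npc, Nenc)."""

    samples: np.ndarray
    trajectory: SpiralTrajectory
    noise_sigma: float = 0.0
    whitened: bool = False

    def __post_init__(self) -> None:
        npts, nsp = self.samples.shape[:2]
        if (npts, nsp) != (self.trajectory.n_points, self.trajectory.n_interleaves):
            raise ValueError("sample dims inconsistent with trajectory")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite k-space samples")

    @property
    def dims(self) -> tuple[int, int, int, int]:
        """(Nch, Nph, Npc, Nenc)."""
        return self.samples.shape[2:]


def design_spiral(
    matrix_size: int,
    fov_mm: float,
    n_interleaves: int = 4,
    n_points: int | None = None,
    allow_undersampled: bool = False,
) -> SpiralTrajectory:
    """Uniform-density Archimedean spiral meeting radial Nyquist.

    k(tau) = k_max * tau * [cos, sin](2 pi n_turns tau + 2 pi m / N_sp),
    n_turns = matrix_size / (2 * N_sp).
    """
    if n_points is None:
        # scale of the high-resolution protocol: 2784 points for a 128 matrix
        n_points = int(round(2784 * matrix_size / 128))
    if n_points < matrix_size and not allow_undersampled:
        raise ValueError(
            f"n_points={n_points} < matrix_size={matrix_size}: undersampled "
            "design; pass allow_undersampled=True to override"
        )
    k_max = matrix_size / (2.0 * fov_mm)
    n_turns = matrix_size / (2.0 * n_interleaves)
    tau = np.linspace(0.0, 1.0, n_points)
    coords = np.empty((n_interleaves, n_points, 2))
    for m in range(n_interleaves):
        ang = 2 * np.pi * n_turns * tau + 2 * np.pi * m / n_interleaves
        coords[m, :, 0] = k_max * tau * np.cos(ang)
        coords[m, :, 1] = k_max * tau * np.sin(ang)
    return SpiralTrajectory(coords=coords, fov_mm=fov_mm, matrix_size=matrix_size)


def make_birdcage_coils(
    grid_size: int,
    fov_mm: float,
    n_coils: int,
    rel_radius: float = 1.2,
    rel_width: float = 0.9,
) -> np.ndarray:
    """Smooth birdcage-style sensitivities: Gaussian falloff + smooth phase."""
    pos = (np.arange(grid_size) - grid_size / 2) * (fov_mm / grid_size)
    xx, yy = np.meshgrid(pos, pos, indexing="ij")
    radius = rel_radius * fov_mm / 2
    width = rel_width * fov_mm / 2
    sens = np.empty((grid_size, grid_size, n_coils), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mag = np.exp(-d2 / (2 * width**2)) + 0.05
        phase = 0.3 * np.pi * ((xx * np.cos(ang) + yy * np.sin(ang)) / fov_mm) + ang / 3
        sens[..., c] = mag * np.exp(1j * phase)
    return sens


def default_noise_cov(n_coils: int, rho: float = 0.3) -> np.ndarray:
    """Exponentially decaying inter-coil correlation rho^|i-j| (Hermitian PD)."""
    idx = np.arange(n_coils)
    return rho ** np.abs(idx[:, None] - idx[None, :]) + 0j


def forward_sample(
    images: np.ndarray,
    traj: SpiralTrajectory,
    coils: CoilModel | None = None,
    nufft: GriddingNufft | None = None,
) -> KSpaceSet:
    """Sample 6D coil images (Nx,Ny,Nch,Nph,Npc,Nenc) along the trajectory.

    ``images`` must already include coil sensitivities (the phantom renders
    them in); ``coils`` is carried for metadata symmetry only.
    """
    n = traj.matrix_size
    if images.shape[:2] != (n, n):
        raise ValueError("image grid does not match trajectory matrix size")
    if nufft is None:
        nufft = GriddingNufft(traj.flat_coords(), n, traj.fov_mm)
    batch = images.reshape(n, n, -1)
    samp = nufft.forward(batch)  # (nsp*npts, B)
    samp = samp.reshape(traj.n_interleaves, traj.n_points, -1)
    samp = np.moveaxis(samp, 0, 1)  # (npts, nsp, B)
    samp = samp.reshape(traj.n_points, traj.n_interleaves, *images.shape[2:])
    return KSpaceSet(samples=samp, trajectory=traj)


def _correlated_noise(
    shape_tail: tuple, n_samples: int, noise_cov: np.ndarray, sigma: float, rng
) -> np.ndarray:
    """Complex Gaussian noise (n_samples, Nch, *tail); per-component std sigma
    scaled by chol(noise_cov) across the coil axis."""
    nch = noise_cov.shape[0]
    chol = np.linalg.cholesky(noise_cov)
    z = rng.standard_normal((n_samples, nch, *shape_tail, 2))
    z = sigma * (z[..., 0] + 1j * z[..., 1])
    return np.einsum("ij,sj...->si...", chol, z)


def add_noise(
    kspace: KSpaceSet, sigma: float, noise_cov: np.ndarray, seed: int
) -> KSpaceSet:
    """Add coil-correlated complex Gaussian noise; deterministic under seed.

    ``sigma`` is the per-real-component standard deviation of each coil's
    noise before the coil correlation is applied (complex variance 2*sigma^2
    per unit diagonal of the covariance).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return KSpaceSet(
            samples=kspace.samples.copy(),
            trajectory=kspace.trajectory,
            noise_sigma=0.0,
            whitened=kspace.whitened,
        )
    rng = np.random.default_rng(seed)
    npts, nsp, nch, nph, npc, nenc = kspace.samples.shape
    noise = _correlated_noise(
        (nph, npc, nenc), npts * nsp, np.asarray(noise_cov), sigma, rng
    )
    noise = noise.reshape(npts, nsp, nch, nph, npc, nenc)
    return KSpaceSet(
        samples=kspace.samples + noise,
        trajectory=kspace.trajectory,
        noise_sigma=sigma,
        whitened=kspace.whitened,
    )


def noise_only_kspace(
    traj: SpiralTrajectory,
    dims: tuple[int, int, int, int],
    noise_cov: np.ndarray,
    sigma: float,
    seed: int,
) -> KSpaceSet:
    """Noise-only k-space with the acquisition's dimensions (Nch,Nph,Npc,Nenc)."""
    zero = KSpaceSet(
        samples=np.zeros((traj.n_points, traj.n_interleaves, *dims), dtype=complex),
        trajectory=traj,
    )
    return add_noise(zero, sigma, noise_cov, seed)
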