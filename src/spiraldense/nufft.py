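"""Gridding NUFFT for 2D non-Cartesian sampling.

Implements the type-2 (image -> nonuniform k-space samples) transform and its
exact adjoint via Kaiser-Bessel interpolation on an oversampled FFT grid. The
forward/adjoint pair is an exact matrix transpose pair by construction: the
same sparse interpolation matrix, the same (unitary up to scale) FFT and the
same real apodization correction appear on both sides, so the inner-product
identity <A x, y> = <x, A^H y> holds to machine precision.

Conventions
-----------
* Image pixels live at x = (i - N/2) * dx mm, dx = fov / N, for i = 0..N-1.
* k-space coordinates are in cycles/mm; the forward model is
  s(k) = sum_x I(x) * exp(-2j*pi * k . x).
* The gridding convolution correlates neighbouring gridded samples -- the very
  effect the Marchenko-Pastur bound calibration in :mod:`spiraldense.bounds`
  is designed to absorb -- so calibration and reconstruction must share one
  operator instance (they do: see :mod:`spiraldense.pipeline`).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import i0


def _kb_kernel(t: np.ndarray, width: float, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel c(t) on |t| <= width/2 (grid units)."""
    r = 1.0 - (2.0 * t / width) ** 2
    out = np.zeros_like(t, dtype=float)
    ok = r > 0
    out[ok] = i0(beta * np.sqrt(r[ok]))
    return out


def _kb_apodization(n: np.ndarray, n_os: int, width: float, beta: float) -> np.ndarray:
    """Fourier transform of the KB kernel at image positions ``n`` (pixels).

    Evaluated at spatial frequency f = (n - n_os/2) / n_os cycles per grid
    unit; the sinh form continues to a sinc form where the radicand flips sign.
    """
    f = (n - n_os / 2.0) / n_os
    z2 = beta**2 - (np.pi * width * f) ** 2
    out = np.empty_like(f, dtype=float)
    pos = z2 > 0
    zp = np.sqrt(z2[pos])
    out[pos] = np.sinh(zp) / zp
    zn = np.sqrt(-z2[~pos])
    with np.errstate(invalid="ignore"):
        out[~pos] = np.where(zn > 0, np.sin(zn) / zn, 1.0)
    return width * out


class GriddingNufft:
    """Kaiser-Bessel gridding NUFFT for a fixed set of 2D sample locations.

    Parameters
    ----------
    coords : (n_samples, 2) float array
        k-space sample locations in cycles/mm (kx, ky).
    matrix_size : int
        Image grid size N (square images).
    fov_mm : float
        Field of view in mm.
    oversampling : float
        Grid oversampling factor (default 2.0).
    kernel_width : int
        Interpolation kernel width in oversampled grid units (default 4).
    """

    def __init__(
        self,
        coords: np.ndarray,
        matrix_size: int,
        fov_mm: float,
        oversampling: float = 2.0,
        kernel_width: int = 4,
    ) -> None:
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        self.coords = coords
        self.n = int(matrix_size)
        self.fov_mm = float(fov_mm)
        self.n_os = int(round(self.n * oversampling))
        self.osf = self.n_os / self.n
        self.width = float(kernel_width)
        # Beatty et al. optimal shape parameter
        self.beta = np.pi * np.sqrt(
            (self.width / self.osf) ** 2 * (self.osf - 0.5) ** 2 - 0.8
        )
        self._interp = self._build_interp_matrix()
        lo = (self.n_os - self.n) // 2
        apod_1d = _kb_apodization(
            np.arange(lo, lo + self.n, dtype=float), self.n_os, self.width, self.beta
        )
        self._apod = np.outer(apod_1d, apod_1d)  # real, strictly positive
        self._pad_lo = lo

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    def _build_interp_matrix(self) -> sp.csr_matrix:
        # grid coordinate of each sample, in oversampled-grid units, centered
        g = self.coords * self.fov_mm * self.osf  # (ns, 2)
        half = int(np.ceil(self.width / 2.0))
        offsets = np.arange(-half + 1, half + 1)  # width nearest points
        ns = g.shape[0]
        base = np.floor(g).astype(int)  # (ns, 2)
        # neighbour indices and kernel weights per axis
        idx = base[:, None, :] + offsets[None, :, None]  # (ns, w, 2)
        t = idx - g[:, None, :]  # signed distance in grid units
        w = _kb_kernel(t, self.width, self.beta)  # (ns, w, 2)
        wx, wy = w[..., 0], w[..., 1]
        ix = np.mod(idx[..., 0], self.n_os)
        iy = np.mod(idx[..., 1], self.n_os)
        # outer product over the two axes -> (ns, w, w)
        weights = (wx[:, :, None] * wy[:, None, :]).reshape(ns, -1)
        cols = (ix[:, :, None] * self.n_os + iy[:, None, :]).reshape(ns, -1)
        rows = np.repeat(np.arange(ns), cols.shape[1])
        mat = sp.csr_matrix(
            (weights.ravel(), (rows, cols.ravel())),
            shape=(ns, self.n_os * self.n_os),
        )
        mat.sum_duplicates()
        return mat

    # -- forward: image -> samples ------------------------------------------------
    def forward(self, images: np.ndarray) -> np.ndarray:
        """Type-2 transform. ``images`` is (N, N) or (N, N, batch)."""
        single = images.ndim == 2
        if single:
            images = images[..., None]
        if images.shape[:2] != (self.n, self.n):
            raise ValueError(
                f"image grid {images.shape[:2]} does not match matrix size {self.n}"
            )
        x = images / self._apod[..., None]
        lo = self._pad_lo
        padded = np.zeros((self.n_os, self.n_os, x.shape[2]), dtype=complex)
        padded[lo : lo + self.n, lo : lo + self.n] = x
        spec = np.fft.fft2(np.fft.ifftshift(padded, axes=(0, 1)), axes=(0, 1))
        out = self._interp @ spec.reshape(self.n_os * self.n_os, -1)
        return out[:, 0] if single else out

    # -- adjoint: samples -> image ------------------------------------------------
    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`. ``samples`` is (ns,) or (ns, batch)."""
        single = samples.ndim == 1
        if single:
            samples = samples[:, None]
        if samples.shape[0] != self.n_samples:
            raise ValueError("sample count does not match trajectory")
        grid = (self._interp.conj().T @ samples).reshape(
            self.n_os, self.n_os, -1
        )
        img = np.fft.fftshift(
            np.fft.ifft2(grid, axes=(0, 1)), axes=(0, 1)
        ) * (self.n_os * self.n_os)
        lo = self._pad_lo
        img = img[lo : lo + self.n, lo : lo + self.n] / self._apod[..., None]
        return img[..., 0] if single else img


def direct_dft(images: np.ndarray, coords: np.ndarray, fov_mm: float) -> np.ndarray:
    """Exact (slow) type-2 nonuniform DFT; test oracle for :class:`GriddingNufft`."""
    single = images.ndim == 2
    if single:
        images = images[..., None]
    n = images.shape[0]
    dx = fov_mm / n
    pos = (np.arange(n) - n / 2) * dx
    xx, yy = np.meshgrid(pos, pos, indexing="ij")
    coords = np.asarray(coords, float).reshape(-1, 2)
    phase = np.exp(
        -2j
        * np.pi
        * (coords[:, 0:1] * xx.ravel()[None, :] + coords[:, 1:2] * yy.ravel()[None, :])
    )
    out = phase @ images.reshape(n * n, -1)
    return out[:, 0] if single else out
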