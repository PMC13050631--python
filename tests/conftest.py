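"""Shared small-scale fixtures.

The unit suite runs on reduced dimensions (32x32 grid, 4 coils, 6 cardiac
phases) so the whole suite stays fast; the physics is size-invariant and the
acceptance tests exercise larger instances where a criterion demands it.
Session scope avoids re-rendering the phantom and re-building the gridding
operator for every test.
"""

from __future__ import annotations

import numpy as np
import pytest

from spiraldense.phantom import PhantomConfig, render_dense_images
from spiraldense.pipeline import Acquisition, AcquisitionConfig, RunConfig, run_pipeline
from spiraldense.recon import apply_prewhitening, estimate_prewhitener
from spiraldense.sampling import forward_sample, noise_only_kspace


@pytest.fixture(scope="session")
def small_phantom() -> PhantomConfig:
    return PhantomConfig(grid_size=32, n_coils=4, n_phases=6)


@pytest.fixture(scope="session")
def small_acq(small_phantom) -> Acquisition:
    return Acquisition(small_phantom, AcquisitionConfig())


@pytest.fixture(scope="session")
def small_truth(small_phantom, small_acq):
    return render_dense_images(small_phantom, small_acq.coils.sensitivities)


@pytest.fixture(scope="session")
def small_noise_free(small_phantom, small_acq, small_truth):
    """Noise-free reference chain: whitener, whitened sensitivities, recon."""
    ph = small_phantom
    acq = small_acq
    ks_ref = forward_sample(
        small_truth.reference_images, acq.trajectory, acq.coils, acq.nufft
    )
    prescan = noise_only_kspace(
        acq.trajectory, (ph.n_coils, 1, 1, 1), acq.coils.noise_cov, 1.0, 900
    )
    whitener = estimate_prewhitener(prescan.samples.reshape(-1, ph.n_coils))
    sens_w = np.einsum("ij,xyj->xyi", whitener, acq.coils.sensitivities)
    img_ref = acq.recon(apply_prewhitening(ks_ref, whitener))
    return {
        "ks_ref": ks_ref,
        "whitener": whitener,
        "sens_w": sens_w,
        "img_ref": img_ref,
    }


@pytest.fixture(scope="session")
def small_run():
    """One full denoising pipeline run at the small scale."""
    cfg = RunConfig(
        phantom=PhantomConfig(grid_size=32, n_coils=4, n_phases=6), seed=5
    )
    return cfg, run_pipeline(cfg)
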