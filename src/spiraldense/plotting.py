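"""Plotting helpers: strain-time curves and magnitude/phase frame export."""

from __future__ import annotations

import numpy as np

from .strain import StrainResult


def plot_strain_time_curves(result: StrainResult, path=None, ax=None):
    """Segmental E_cc strain-time curves with +/- 1 SD bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frames = np.arange(result.segment_means.shape[1])
    for s, label in enumerate(result.segment_labels):
        mean = result.segment_means[s]
        sd = result.segment_sds[s]
        ax.plot(frames, mean, label=label)
        ax.fill_between(frames, mean - sd, mean + sd, alpha=0.15)
    ax.set_xlabel("cardiac phase")
    ax.set_ylabel("$E_{cc}$")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def export_frames(magnitude: np.ndarray, prefix: str) -> list:
    """Write per-frame magnitude PNGs; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for f in range(magnitude.shape[2]):
        fig, ax = plt.subplots()
        ax.imshow(magnitude[:, :, f].T, cmap="gray", origin="lower")
        ax.axis("off")
        out = f"{prefix}_frame{f:03d}.png"
        fig.savefig(out, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(out)
    return paths
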