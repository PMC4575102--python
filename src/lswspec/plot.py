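"""Minimal plotting helper for spectrum estimates."""

from __future__ import annotations

import numpy as np

from .pipeline import SpectrumEstimate

__all__ = ["plot_spectrum"]


def plot_spectrum(
    est: SpectrumEstimate,
    scales: list[int] | None = None,
    truth: np.ndarray | None = None,
    ax=None,
):
    """Plot per-scale spectrum estimates with shaded credible bands.

    ``scales`` are process scales (1 = finest); one panel per scale.
    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    J, T = est.point.shape
    scales = scales or list(range(1, min(J, 4) + 1))
    z = np.arange(T) / T
    if ax is None:
        fig, axes = plt.subplots(len(scales), 1, sharex=True, figsize=(8, 2.2 * len(scales)))
    else:
        fig, axes = ax.figure, [ax]
    axes = np.atleast_1d(axes)
    for a, j in zip(axes, scales):
        for q, (lo, hi) in sorted(est.bands.items(), reverse=True):
            a.fill_between(z, lo[j - 1], hi[j - 1], alpha=0.3, color="grey",
                           label=f"{round(q * 100)}% band")
        a.plot(z, est.point[j - 1], "b--", lw=1, label="estimate")
        if truth is not None:
            a.plot(z, truth[j - 1], "k-", lw=1, label="truth")
        a.set_ylabel(f"$S_{{{j}}}(z)$")
    axes[-1].set_xlabel("rescaled time z")
    axes[0].legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    return fig
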