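"""Plot helpers for moment curves and agreement diagnostics."""

from __future__ import annotations

import numpy as np

from .types import NetMomentSeries

_AXIS_LABELS = {
    "Mx": "Mx (latflex left +) [Nm]",
    "My": "My (flexion +) [Nm]",
    "Mz": "Mz (rotation left +) [Nm]",
}


def plot_moment_comparison(
    estimated: NetMomentSeries,
    target: NetMomentSeries | None = None,
    title: str | None = None,
):
    """Three-axis moment curves, estimated vs (optional) target.

    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 6))
    for ax, comp in zip(axes, ("Mx", "My", "Mz")):
        ax.plot(estimated.t, getattr(estimated, comp), label="estimated", lw=1.0)
        if target is not None:
            ax.plot(target.t, getattr(target, comp), label="target", lw=1.0, alpha=0.7)
        ax.set_ylabel(_AXIS_LABELS[comp])
        ax.axhline(0.0, color="k", lw=0.5, alpha=0.4)
    axes[-1].set_xlabel("time [s]")
    axes[0].legend(loc="upper right")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_norm_by_task(moments_by_task: dict[str, NetMomentSeries]):
    """Moment-norm traces per work task (light / heavy / static / dynamic)."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for label, m in moments_by_task.items():
        ax.plot(m.t, m.norm, label=f"{label} (mean {np.mean(m.norm):.1f} Nm)", lw=1.0)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("||M|| [Nm]")
    ax.legend()
    fig.tight_layout()
    return fig


__all__ = ["plot_moment_comparison", "plot_norm_by_task"]
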