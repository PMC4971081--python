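"""Quick-look figures: module electrophysiology and ROI-level series.

Matplotlib helpers for the two standard views of a run: per-module mean
electrical activity with the host node's background trace, and ROI-level
ISA/BOLD time series with block shading.
"""

from __future__ import annotations

import numpy as np

from .experiment import ExperimentDesign, Recordings

__all__ = ["plot_module_activity", "plot_series"]


def _shade_blocks(ax, design: ExperimentDesign) -> None:
    for onset, cond in design.block_onsets():
        if cond == "DMS":
            ax.axvspan(onset, onset + 16.5, color="0.9", zorder=0)


def plot_module_activity(
    rec: Recordings,
    design: ExperimentDesign | None = None,
    modules: list[str] | None = None,
    t_max_s: float | None = None,
):
    """One row per module: mean unit activity (task) and host-node activity
    (background noise).  Returns the matplotlib Figure."""
    import matplotlib.pyplot as plt

    design = design or rec.design
    modules = modules or rec.module_names
    t = np.arange(rec.n_steps) * rec.dt_ms / 1000.0
    sl = slice(None) if t_max_s is None else slice(0, int(t_max_s * 1000 / rec.dt_ms))

    fig, axes = plt.subplots(
        len(modules), 1, figsize=(10, 1.1 * len(modules)), sharex=True, squeeze=False
    )
    for ax, name in zip(axes[:, 0], modules):
        ax.plot(t[sl], rec.module_E(name)[sl].mean(axis=1), lw=0.6, color="crimson")
        host = rec.host_nodes.get(name)
        if host is not None:
            ax.plot(t[sl], rec.tvb_E[sl, host], lw=0.4, color="steelblue", alpha=0.8)
        if design is not None:
            _shade_blocks(ax, design)
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel(name, rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    return fig


def plot_series(
    series: dict[str, np.ndarray],
    interval_s: float,
    design: ExperimentDesign | None = None,
    title: str = "",
):
    """Stacked ROI series (ISA or BOLD) on a common time axis."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for name, vals in series.items():
        t = np.arange(len(vals)) * interval_s
        ax.plot(t, vals, lw=0.8, label=name)
    if design is not None:
        _shade_blocks(ax, design)
    ax.set_xlabel("time (s)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8, ncol=2)
    fig.tight_layout()
    return fig
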