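"""Optional quick-look figures for the three protocol analyses.

Panel layouts follow the conventions of the isolated-muscle literature:
preload on the x-axis for force-length characteristics, twitch-by-twitch
percent time courses for the slow force response, and post-pause beat
number for post-rest potentiation.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 -- headless by default
import matplotlib.pyplot as plt
import numpy as np

from .protocols import FLResult, PRPResult, SFRResult

__all__ = ["plot_fl", "plot_sfr", "plot_prp"]

_FL_PANELS = (
    ("active_tension_mN_mm2", "Active tension (mN/mm$^2$)"),
    ("passive_tension_mN_mm2", "Passive tension (mN/mm$^2$)"),
    ("force_ttp_ms", "Force TTP (ms)"),
    ("force_t50_ms", "Force T50 (ms)"),
    ("cat_ttp_ms", "CaT TTP (ms)"),
    ("cat_t50_ms", "CaT T50 (ms)"),
)


def plot_fl(results: dict, path=None):
    """Preload-dependent characteristics; ``results`` maps a label (e.g.
    group name) to an :class:`FLResult`."""
    fig, axes = plt.subplots(3, 2, figsize=(8, 9), sharex=True)
    for label, res in results.items():
        tab = res.table
        for ax, (col, ylab) in zip(axes.ravel(), _FL_PANELS):
            ax.plot(tab["preload_pct"], tab[col], "o-", label=label)
            ax.set_ylabel(ylab)
    for ax in axes[-1]:
        ax.set_xlabel("Preload (% $L_{max}$)")
    axes[0, 0].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sfr(results: dict, path=None):
    """Percent time courses of the slow force response."""
    names = ("force_amplitude", "force_ttp", "force_t50",
             "cat_diastolic", "cat_amplitude", "cat_t50")
    fig, axes = plt.subplots(3, 2, figsize=(8, 9), sharex=True)
    for label, res in results.items():
        for ax, name in zip(axes.ravel(), names):
            ax.plot(res.beat_times_s, res.series[name], lw=0.8, label=label)
            ax.axhline(100.0, ls=":", c="k", lw=0.6)
            ax.set_ylabel(f"{name} (%)")
    for ax in axes[-1]:
        ax.set_xlabel("Time after stretch (s)")
    axes[0, 0].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_prp(results: dict, path=None):
    """Post-pause percent series (force amplitude, CaT diastolic/amplitude)."""
    names = ("force_amplitude", "cat_diastolic", "cat_amplitude")
    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
    for label, res in results.items():
        for ax, name in zip(axes, names):
            beats = np.arange(len(res.series[name]))
            ax.plot(beats, res.series[name], "o-", ms=3, label=label)
            ax.axhline(100.0, ls=":", c="k", lw=0.6)
            ax.set_ylabel(f"{name} (%)")
    axes[-1].set_xlabel("Post-pause beat")
    axes[0].legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
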