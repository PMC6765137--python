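"""Diagnostic plots: learned error rates by quality, and the raw-read
error profile by type and position."""

from __future__ import annotations

import numpy as np

from .errormodel import ErrorModel, TransitionCounts
from .mockeval import ErrorProfile

__all__ = ["plot_error_rates", "plot_error_profile"]

_NT = "ACGT"


def plot_error_rates(model: ErrorModel, counts: TransitionCounts | None = None,
                     path=None):
    """Modeled (and optionally observed) error rate vs quality score.

    One panel per true nucleotide, one line per error transition, log
    scale. Observed raw rates from ``counts`` are overlaid as points.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qs = np.arange(94)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True, sharey=True)
    for t, ax in enumerate(axes.ravel()):
        for o in range(4):
            if o == t:
                continue
            ax.plot(qs, model.rates[t, o], label=f"{_NT[t]}→{_NT[o]}")
            if counts is not None:
                tot = counts.counts[t].sum(axis=0)
                seen = tot > 0
                obs = np.where(seen, counts.counts[t, o] / np.maximum(tot, 1),
                               np.nan)
                ax.plot(qs[seen], obs[seen], ".", ms=3, alpha=0.5)
        ax.set_yscale("log")
        ax.set_title(f"true {_NT[t]}")
        ax.legend(fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("quality score")
    for ax in axes[:, 0]:
        ax.set_ylabel("error rate")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_error_profile(profile: ErrorProfile, path=None, max_pos=None):
    """Error rate by read position, one panel per error type.

    Substitution and insertion points are shaded by quality (darker =
    lower quality); deletions carry no quality.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_reads = max(profile.n_reads, 1)
    panels = [("substitution", profile.substitutions),
              ("insertion", profile.insertions),
              ("deletion", profile.deletions)]
    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    for ax, (name, tallies) in zip(axes, panels):
        if name == "deletion":
            pos = np.array(sorted(tallies))
            rate = np.array([tallies[p] for p in pos]) / n_reads
            if len(pos):
                ax.scatter(pos, rate, s=8, c="k")
        else:
            pts = sorted(tallies.items())
            if pts:
                pos = np.array([p for (p, _), _ in pts])
                q = np.array([qq for (_, qq), _ in pts])
                rate = np.array([n for _, n in pts]) / n_reads
                sc = ax.scatter(pos, rate, s=8, c=q, cmap="viridis_r",
                                vmin=0, vmax=93)
                fig.colorbar(sc, ax=ax, label="quality")
        ax.set_ylabel(f"{name} rate")
        if max_pos:
            ax.set_xlim(0, max_pos)
    axes[-1].set_xlabel("position in read (nt)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
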