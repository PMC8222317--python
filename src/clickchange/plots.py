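"""Simple diagnostic figures: psychometric curves, false-alarm rates, and
reverse-correlation kernels."""

from __future__ import annotations

import numpy as np

from .metrics import PsychometricSummary
from .revcorr import KernelResult

__all__ = ["plot_psychometric", "plot_kernel"]


def plot_psychometric(summaries: dict[str, PsychometricSummary], ax=None):
    """Hit rate vs |delta| with binomial CIs and fitted thresholds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, s in summaries.items():
        err = np.vstack([s.hit_rates - s.ci_low, s.ci_high - s.hit_rates])
        line = ax.errorbar(s.deltas, s.hit_rates, yerr=err, marker="o",
                           capsize=3, label=cond)
        if np.isfinite(s.threshold):
            ax.axvline(abs(s.threshold), ls="--", lw=0.8,
                       color=line.lines[0].get_color())
    ax.axhline(0.5, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("|rate change| (Hz)")
    ax.set_ylabel("hit rate")
    ax.set_ylim(0, 1)
    ax.legend(fontsize="small")
    return ax


def plot_kernel(kernel: KernelResult, ax=None, baseline: float = 60.0):
    """Response-aligned detection kernel with its SEM band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(kernel.t, kernel.mean_rate - kernel.sem,
                    kernel.mean_rate + kernel.sem, alpha=0.3)
    ax.plot(kernel.t, kernel.mean_rate, label=kernel.condition)
    ax.axhline(baseline, ls="--", color="gray", lw=0.8)
    if kernel.start_defined and np.isfinite(kernel.start_time):
        ax.axvline(kernel.start_time, ls=":", lw=0.8)
    ax.set_xlabel("time from response (s)")
    ax.set_ylabel("click rate (Hz)")
    ax.legend(fontsize="small")
    return ax
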