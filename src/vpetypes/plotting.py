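"""Optional static plots: correlograms and peri-event histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .correlograms import Correlogram  # noqa: E402
from .responses import Peth  # noqa: E402


def plot_correlogram(c: Correlogram, ax=None, color="k"):
    """Bar plot of a correlogram with its surrogate bands, if present."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(c.lags, c.counts, width=c.bin_ms, color=color)
    if c.ci_upper is not None:
        ax.fill_between(c.lags, c.ci_lower, c.ci_upper, color="0.7", alpha=0.6,
                        label="surrogate 95% band")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("coincidences")
    return ax


def plot_peth(peth: Peth, ax=None, zscored=False, color="tab:blue"):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    y = peth.z if (zscored and peth.z is not None) else peth.rate
    ax.plot(peth.bin_centers, y, color=color)
    ax.axvline(0.0, color="0.5", lw=0.8)
    ax.set_xlabel("time from event (s)")
    ax.set_ylabel("Z" if zscored else "rate (Hz)")
    if peth.event_label:
        ax.set_title(peth.event_label, fontsize=9)
    return ax
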