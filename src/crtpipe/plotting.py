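"""Convenience plots for conditioned CRT series and binned densities.

These mirror the standard presentation of automated-CRT results: refill time
and sensor temperature versus time with quality indices above, and a 2-D
density of refill time versus temperature with the best-fit line overlaid.
Aesthetics are deliberately plain.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .postprocess import CRTSeries  # noqa: E402
from .stats import BinnedDensity  # noqa: E402

_COLORS = {520: "tab:green", 640: "tab:red", 950: "tab:blue"}


def plot_crt_series(series: dict[int, CRTSeries], temperature=None):
    """Refill time (filtered) per wavelength vs time, with the used-refill
    percentage quality index in an upper panel."""
    fig, (ax_q, ax) = plt.subplots(
        2, 1, sharex=True, figsize=(9, 6), height_ratios=[1, 3]
    )
    for w, s in sorted(series.items()):
        if len(s.resampled_times) == 0:
            continue
        c = _COLORS.get(w, None)
        ax.plot(s.resampled_times, s.filtered_crt, color=c, label=f"{w} nm")
        if len(s.used_fraction):
            ax_q.plot(s.resampled_times, s.used_fraction, color=c)
    if temperature is not None:
        t, temp = temperature
        ax_t = ax.twinx()
        ax_t.plot(t, temp, color="k", alpha=0.4, lw=0.8)
        ax_t.set_ylabel("temperature (degC)")
    ax_q.set_ylabel("used refills (%)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("refill time (s)")
    ax.legend(loc="best")
    fig.tight_layout()
    return fig


def plot_binned_density(density: BinnedDensity):
    """CRT vs temperature density with the unbinned best-fit line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.pcolormesh(
        density.temp_bin_edges, density.crt_bin_edges, density.counts, cmap="viridis"
    )
    t = np.array([density.temp_bin_edges[0], density.temp_bin_edges[-1]])
    ax.plot(t, density.fit_intercept + density.fit_slope * t, "w:", lw=2)
    ax.set_xlabel("sensor temperature (degC)")
    ax.set_ylabel("refill time (s)")
    fig.tight_layout()
    return fig
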