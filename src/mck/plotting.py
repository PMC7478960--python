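"""Small matplotlib helpers for the main result objects."""

from __future__ import annotations

import numpy as np

from .contact import ContactSeries
from .linescan import Linescan, ShiftCurve
from .tracking import Kymograph, MsdFit


def plot_shift_curve(curve: ShiftCurve, ax=None):
    """Mean correlation vs shift with the SEM band and threshold markers."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    d, m, s = curve.shift_distances, curve.mean_correlation, curve.dispersion
    ax.axhline(0, color="0.7", lw=0.8)
    ax.fill_between(d, m - s, m + s, alpha=0.3, label="mean ± SEM")
    ax.plot(d, m, "-o", ms=3)
    if curve.threshold_distance:
        for sign in (-1, 1):
            ax.axvline(sign * curve.threshold_distance, ls=":", color="b")
    ax.set_xlabel("shift (nm)")
    ax.set_ylabel("Pearson correlation")
    return ax


def plot_linescan(scan: Linescan, ax=None):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    for name, prof in scan.channel_profiles.items():
        rng = np.ptp(prof)
        ax.plot(scan.arc_positions / 1000.0,
                (prof - prof.min()) / rng if rng else prof, label=name)
    ax.set_xlabel("arc position (µm)")
    ax.set_ylabel("relative intensity")
    ax.legend()
    return ax


def plot_msd_fit(fit: MsdFit, ax=None):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    ax.loglog(fit.lags, fit.msd, "o", ms=3, label="MSD")
    i0, i1 = fit.fit_range
    lags = fit.lags[i0:i1]
    ax.loglog(lags, np.exp(fit.log_intercept) * lags ** fit.alpha, "-",
              label=f"α = {fit.alpha:.2f}")
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("MSD (nm²)")
    ax.legend()
    return ax


def plot_contact_series(series: ContactSeries, ax=None):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    t = np.arange(len(series.r_values)) * series.frame_interval
    ax.plot(t, series.r_values, "-o", ms=3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("colocalization ratio R")
    ax.set_ylim(0, 1)
    return ax


def plot_kymograph(kymo: Kymograph, ax=None):
    """Position (x) against time (y, top to bottom)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    arc = kymo.line.arc_positions()
    extent = [arc[0] / 1000, arc[-1] / 1000,
              kymo.values.shape[0] * kymo.frame_interval, 0]
    ax.imshow(kymo.values, aspect="auto", extent=extent, cmap="gray")
    ax.set_xlabel("position (µm)")
    ax.set_ylabel("time (s)")
    return ax
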