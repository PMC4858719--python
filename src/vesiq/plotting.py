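"""Plot helpers for size/intensity distributions (semi-logarithmic axes)."""

from __future__ import annotations

import numpy as np

from .core import DistributionFit


def plot_histogram_with_fit(hist_frame, fit: DistributionFit | None = None,
                            log_x: bool = False, ax=None, xlabel="", ylabel="mean count"):
    """Plot a per-vessel mean ± SEM histogram with an optional log-normal fit.

    ``hist_frame`` is the output of :func:`vesiq.radius_histogram` or
    :func:`vesiq.intensity_histogram`. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centres = np.sqrt(hist_frame["bin_left"] * hist_frame["bin_right"]) if log_x \
        else 0.5 * (hist_frame["bin_left"] + hist_frame["bin_right"])
    ax.errorbar(centres, hist_frame["mean_count"], yerr=hist_frame["sem_count"],
                fmt="o", ms=4, capsize=2)
    if fit is not None:
        total = hist_frame["mean_count"].sum()
        x = np.geomspace(hist_frame["bin_left"].iloc[0], hist_frame["bin_right"].iloc[-1], 200) \
            if log_x else np.linspace(hist_frame["bin_left"].iloc[0],
                                      hist_frame["bin_right"].iloc[-1], 200)
        pdf = np.exp(-0.5 * ((np.log(x) - fit.mu_ln) / fit.sigma_ln) ** 2) / (
            x * fit.sigma_ln * np.sqrt(2 * np.pi))
        widths = np.diff(hist_frame["bin_left"]).mean() if not log_x else None
        if log_x:
            # expected count per log-spaced bin: pdf * x * d(ln x) * total
            dlnx = np.log(hist_frame["bin_right"].iloc[0] / hist_frame["bin_left"].iloc[0])
            ax.plot(x, pdf * x * dlnx * total, "-")
            ax.set_xscale("log")
        else:
            ax.plot(x, pdf * widths * total, "-")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax
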