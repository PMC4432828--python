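"""Figure helpers for the amplicon analysis (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_cg_histograms(values_by_sample: dict, bin_width: float = 1.0, ax=None):
    """Overlaid normalised per-read CG% histograms, one line per sample."""
    import matplotlib.pyplot as plt

    from .amplicon import distribution_summary

    if ax is None:
        _, ax = plt.subplots()
    for name, values in values_by_sample.items():
        hist = distribution_summary(values, bin_width)
        centers = (hist["bin_left"] + hist["bin_right"]) / 2
        ax.plot(centers, hist["share"], marker="o", ms=3, label=name)
    ax.set_xlabel("CG frequency per read (%)")
    ax.set_ylabel("relative frequency")
    ax.legend()
    return ax


def plot_mixture_fit(values, fit, bin_width: float = 0.5, ax=None):
    """Histogram of per-read CG% with the selected Gaussian fit overlaid."""
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(values, dtype=float)
    ax.hist(x, bins=np.arange(0, x.max() + bin_width, bin_width),
            density=True, alpha=0.4, label="data")
    grid = np.linspace(x.min(), x.max(), 400)
    density = np.zeros_like(grid)
    for w, mu, sd in zip(fit.weights, fit.means, fit.sds):
        density += w * norm.pdf(grid, mu, sd)
    ax.plot(grid, density, lw=2, label=f"k={fit.k_selected} fit")
    ax.set_xlabel("CG frequency per read (%)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_cg_tg(per_read_rows, ols=None, ax=None):
    """CG% vs TG% scatter with the fitted regression line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = per_read_rows["cg_pct"].to_numpy()
    y = per_read_rows["tg_pct"].to_numpy()
    ax.scatter(x, y, s=4, alpha=0.4)
    if ols is not None:
        grid = np.linspace(x.min(), x.max(), 2)
        ax.plot(grid, ols.intercept + ols.slope * grid, "r-",
                label=f"slope {ols.slope:.2f}, R²={ols.r_squared:.2f}")
        ax.legend()
    ax.set_xlabel("CG frequency per read (%)")
    ax.set_ylabel("TG frequency per read (%)")
    return ax
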