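"""Plotting helpers for the model outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .model import SplineFit, group_summary


def plot_age_spline(spline: SplineFit, ax=None):
    """Fitted smoothing-spline trend of adjusted counts against maternal age."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spline.grid, spline.fitted, color="C0")
    ax.axvline(spline.argmin_age, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("maternal age (months)")
    ax.set_ylabel("adjusted crossover count")
    return ax


def plot_age_groups(y, groups, ax=None):
    """Dot-and-bar plot of group means with standard errors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    summ = group_summary(y, groups)
    ax.errorbar(summ["group"], summ["mean"], yerr=summ["se"],
                fmt="o", color="C0", capsize=3)
    ax.set_xlabel("maternal age group")
    ax.set_ylabel("adjusted crossover count")
    return ax


def plot_temperature_boxes(y, categories, ax=None):
    """Boxplot of adjusted counts per temperature category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = np.asarray(y, dtype=float)
    cats = np.asarray(categories, dtype=object)
    levels = [l for l in ("cold", "normal", "hot") if (cats == l).any()]
    ax.boxplot([y[cats == l] for l in levels], tick_labels=levels, showmeans=True)
    ax.set_ylabel("adjusted crossover count")
    return ax
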