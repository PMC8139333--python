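"""Diagnostic plots for the main analysis outputs."""

from __future__ import annotations

import numpy as np

from .deep_color import ColorProfile
from .deep_shape import ShapeClustering
from .gpa import GPAResult


def plot_landmark_variability(gpa: GPAResult, ax=None):
    """Per-landmark SD profile with the mean-SD reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sd = gpa.per_landmark_sd
    ax.plot(np.arange(sd.size), sd, marker="o", ms=3, lw=1)
    ax.axhline(sd.mean(), ls=":", color="k", label="mean SD")
    ax.set_xlabel("landmark")
    ax.set_ylabel("SD of aligned position")
    ax.legend()
    return ax


def plot_silhouette_by_k(clustering: ShapeClustering, ax=None):
    """Silhouette score across the candidate numbers of shape clusters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ks = clustering.k_grid
    ax.plot(ks, [clustering.silhouette_by_k[k] for k in ks], marker="o")
    ax.axvline(clustering.best_k, ls=":", color="k")
    ax.set_xlabel("k")
    ax.set_ylabel("mean silhouette")
    return ax


def plot_color_profile(profile: ColorProfile, ax=None):
    """Bar chart of surface percentages per reference color."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = list(profile.percent)
    vals = [profile.percent[n] for n in names]
    colors = {"orange_like": "#C66323", "quasired": "#B82E08", "pale": "#C2904E", "green": "#4C4B14"}
    ax.bar(names, vals, color=[colors.get(n, "gray") for n in names])
    ax.set_ylabel("% of fruit surface")
    ax.set_ylim(0, 100)
    return ax
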