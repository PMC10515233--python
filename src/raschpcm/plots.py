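"""Diagnostic figures: Wright map, TIF/PSI curve, first-contrast scatter,
item probability curves."""

from __future__ import annotations

import numpy as np

from .model import ItemParameters
from .pcm import category_probability
from .targeting_reliability import ReliabilityProfile, TargetingSummary


def wright_map(ts: TargetingSummary, ax=None):
    """Person and item-threshold histograms on the shared logit scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    counts_p, edges = ts.person_hist
    counts_t, _ = ts.threshold_hist
    centers = (edges[:-1] + edges[1:]) / 2
    width = edges[1] - edges[0]
    ax.bar(centers, counts_p, width=width, alpha=0.6, label="persons")
    ax.bar(centers, -counts_t, width=width, alpha=0.6, label="item thresholds")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("location (logits)")
    ax.set_ylabel("count")
    ax.legend()
    ax.set_title(
        f"targeting: persons M={ts.person_mean:.2f} (SD={ts.person_sd:.2f}), "
        f"items M={ts.item_location_mean:.2f}"
    )
    return ax


def plot_tif(profile: ReliabilityProfile, ax=None):
    """Test information with the PSI threshold band marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile.grid, profile.tif, label="test information")
    from .targeting_reliability import information_for_psi

    ti_ref = information_for_psi(profile.psi_threshold)
    ax.axhline(ti_ref, ls="--", color="grey",
               label=f"TI {ti_ref:.2f} (PSI {profile.psi_threshold})")
    for a, b in profile.intervals:
        ax.axvspan(a, b, alpha=0.15, color="green")
    ax.set_xlabel("location (logits)")
    ax.set_ylabel("information")
    ax.legend()
    return ax


def plot_first_contrast(loadings, locations, ax=None):
    """Scatter of item location vs first-contrast loading, labelled by item."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(locations, loadings)
    for iid, x, y in zip(loadings.index, locations, loadings):
        ax.annotate(iid, (x, y), fontsize=8,
                    textcoords="offset points", xytext=(4, 2))
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("item location (logits)")
    ax.set_ylabel("first-contrast loading")
    return ax


def item_probability_curves(ip: ItemParameters, item: str, ax=None,
                            theta_range=(-5, 5)):
    """Category probability curves for one item over a theta grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    th = ip.thresholds[ip.item_ids.index(item)]
    grid = np.linspace(*theta_range, 400)
    p = category_probability(grid, th)
    for x in range(p.shape[1]):
        ax.plot(grid, p[:, x], label=str(x))
    ax.set_xlabel("location (logits)")
    ax.set_ylabel("category probability")
    ax.set_title(item)
    ax.legend(title="category", fontsize=8)
    return ax
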