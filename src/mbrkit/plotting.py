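"""Plot helpers: binned trajectory panels and HDX difference plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .geometry import GeomSeries, bin_series

_PANEL_LABELS = {
    "hlx": "helical content hlx",
    "theta": "tilt angle (deg)",
    "d": "insertion depth d (A)",
    "sasa_buried": "buried SASA (A$^2$)",
}


def plot_geometry(series_df: pd.DataFrame, bin_width_ns: float, path) -> None:
    """Stacked binned panels (mean line, +/- s.d. band) per observable."""
    observables = [o for o in _PANEL_LABELS if o in set(series_df["observable"])]
    fig, axes = plt.subplots(len(observables), 1, sharex=True,
                             figsize=(7, 2.2 * len(observables)))
    if len(observables) == 1:
        axes = [axes]
    for ax, obs in zip(axes, observables):
        for variant, grp in series_df[series_df["observable"] == obs].groupby(
                "variant", sort=False):
            binned = bin_series(
                GeomSeries(obs, grp["time_ps"].to_numpy(),
                           grp["value"].to_numpy()), bin_width_ns)
            ax.plot(binned.bin_centers_ns, binned.bin_means, label=variant)
            ax.fill_between(binned.bin_centers_ns,
                            binned.bin_means - binned.bin_sds,
                            binned.bin_means + binned.bin_sds, alpha=0.25)
        ax.set_ylabel(_PANEL_LABELS[obs])
    axes[0].legend(frameon=False, ncol=3)
    axes[-1].set_xlabel("time (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_difference(diff_df: pd.DataFrame, threshold_Da: float, path) -> None:
    """Per-peptide uptake-difference bars with the threshold lines drawn."""
    fig, axes = plt.subplots(
        len(diff_df["timepoint_s"].unique()), 1, sharex=True, sharey=True,
        figsize=(7, 2.0 * diff_df["timepoint_s"].nunique()))
    timepoints = sorted(diff_df["timepoint_s"].unique())
    if len(timepoints) == 1:
        axes = [axes]
    for ax, tp in zip(axes, timepoints):
        sub = diff_df[diff_df["timepoint_s"] == tp].sort_values("start")
        centers = (sub["start"] + sub["end"]) / 2.0
        widths = sub["end"] - sub["start"] + 1
        colors = ["tab:red" if m else "tab:gray" for m in sub["meaningful"]]
        ax.bar(centers, sub["delta_Da"], width=widths * 0.9, color=colors)
        for y in (threshold_Da, -threshold_Da):
            ax.axhline(y, linestyle=":", color="k", linewidth=0.8)
        ax.axhline(0, color="k", linewidth=0.8)
        ax.set_ylabel(f"{tp:g} s\ndelta (Da)")
    axes[-1].set_xlabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
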