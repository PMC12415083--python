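"""Figures: distance heat maps, region maps, regional bar plots.

All functions take fitted results and return the matplotlib Figure; the
pipeline saves them as PNG.  Axes are in μm with the image convention
(y increasing downward), matching viewer exports.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .distance import AbundanceDistanceFit, DistanceMap
from .regions import RegionAssignment

__all__ = ["plot_distance_map", "plot_abundance_distance", "plot_region_map", "plot_region_percentages"]

REGION_CMAP = plt.get_cmap("tab10")
GRID_UM = 2000.0  # 2 mm grid marks on region maps


def plot_distance_map(dmap: DistanceMap, case_id: str, ax=None):
    """Scatter of source cells colored by nearest-target distance (heat)."""
    sub = dmap.df[dmap.df["case_id"] == case_id]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        sub["x_um"], sub["y_um"], c=sub["distance_um"], cmap="coolwarm_r", s=4
    )
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_title(f"{case_id}: {dmap.source_type} → nearest {dmap.target_type}")
    plt.colorbar(sc, ax=ax, label="distance (μm)")
    return ax.figure


def plot_abundance_distance(fit: AbundanceDistanceFit, ax=None):
    """Log–log scatter of abundance vs median distance with best-fit line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pc = fit.per_case
    ax.scatter(pc["median_distance_um"], pc["target_fraction_pct"], s=20)
    for _, row in pc.iterrows():
        ax.annotate(row["case_id"], (row["median_distance_um"], row["target_fraction_pct"]), fontsize=7)
    xs = np.geomspace(pc["median_distance_um"].min(), pc["median_distance_um"].max(), 50)
    ax.plot(xs, fit.predict_pct(xs), "k--", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("median nearest-T-cell distance (μm)")
    ax.set_ylabel("T cells (% of total cells)")
    ax.set_title(f"slope={fit.slope:.2f}, r²={fit.r_squared:.2f}")
    return ax.figure


def plot_region_map(assignment: RegionAssignment, table, case_id: str, ax=None):
    """x–y scatter of one case's cells colored by region, 2 mm grid."""
    df = table.df.merge(assignment.df[["cell_id", "region_id"]], on="cell_id")
    sub = df[df["case_id"] == case_id]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for rid in sorted(sub["region_id"].unique()):
        r = sub[sub["region_id"] == rid]
        ax.scatter(r["x_um"], r["y_um"], s=3, color=REGION_CMAP((rid - 1) % 10), label=f"region {rid}")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.xaxis.set_major_locator(plt.MultipleLocator(GRID_UM))
    ax.yaxis.set_major_locator(plt.MultipleLocator(GRID_UM))
    ax.grid(True, lw=0.3)
    ax.legend(fontsize=6, markerscale=3)
    ax.set_title(f"{case_id}: {assignment.k} regions")
    return ax.figure


def plot_region_percentages(percentages: pd.DataFrame, ax=None):
    """Stacked bar of region percentages per case."""
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(percentages)), 4))
    bottom = np.zeros(len(percentages))
    for rid in percentages.columns:
        ax.bar(
            percentages.index.astype(str),
            percentages[rid],
            bottom=bottom,
            color=REGION_CMAP((int(rid) - 1) % 10),
            label=f"region {rid}",
        )
        bottom += percentages[rid].to_numpy()
    ax.set_ylabel("% of cells")
    ax.legend(fontsize=7)
    return ax.figure
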