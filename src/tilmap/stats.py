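"""Regional statistics: percentages, areas, densities, ratios, fold changes.

Once every cell is assigned to a region, the analysis reports, per case:

* the fraction of cells falling in each region,
* each region's tissue area (estimated from the cells themselves, since
  region membership is defined on cells, not pixels),
* per-cell-type counts and densities per region, with the total-CD8
  density (both T-cell subsets pooled) as the headline TIL read-out,
* epithelial:stromal density ratios per immune subset, and
* fold changes of mean neighborhood abundance between region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import DEFAULT_CELL_TYPES, CellTable
from .neighborhood import NeighborhoodProfiles
from .regions import RegionAssignment

__all__ = [
    "RegionStats",
    "region_percentages",
    "estimate_region_area",
    "densities_and_ratios",
    "fold_change_matrix",
]

T_NEG, T_POS = DEFAULT_CELL_TYPES[0], DEFAULT_CELL_TYPES[1]
IMMUNE_SUBSETS = DEFAULT_CELL_TYPES[:3]

#: Pseudo-count added to mean neighborhood abundances in fold changes, so
#: immune-poor regions do not divide by zero.
FOLD_CHANGE_PSEUDOCOUNT = 0.01


def _merged(assignment: RegionAssignment, table: CellTable) -> pd.DataFrame:
    adf = assignment.df.set_index("cell_id")
    if set(adf.index) != set(table.df["cell_id"]):
        raise ValueError("assignment does not cover exactly the cells in the table")
    df = table.df.copy()
    df["region_id"] = adf.loc[df["cell_id"], "region_id"].to_numpy(dtype=int)
    df["compartment"] = adf.loc[df["cell_id"], "compartment"].to_numpy()
    return df


def region_percentages(assignment: RegionAssignment, table: CellTable) -> pd.DataFrame:
    """Percent of each case's cells in each region (rows sum to 100)."""
    df = _merged(assignment, table)
    counts = (
        df.groupby(["case_id", "region_id"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(1, assignment.k + 1), fill_value=0)
    )
    return 100.0 * counts.div(counts.sum(axis=1), axis=0)


def estimate_region_area(
    assignment: RegionAssignment,
    table: CellTable,
    pixel_um: float = 5.0,
    halo_um: float = 15.0,
) -> pd.DataFrame:
    """Estimate each region's tissue area per case, in mm².

    The case bounding box (padded by ``halo_um``) is rasterized at
    ``pixel_um``; each pixel within ``halo_um`` of at least one cell is
    attributed to the region of its nearest cell, and the region area is
    the attributed pixel count times the pixel area.  Pixels farther than
    ``halo_um`` from every cell are background.  Empty regions get area
    0.  A case whose cells are all coincident degenerates to (at least) a
    single halo disk, never to zero area.
    """
    df = _merged(assignment, table)
    px_mm2 = (pixel_um / 1000.0) ** 2
    out = {}
    for case_id, sub in df.groupby("case_id", sort=False):
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        regions = sub["region_id"].to_numpy(dtype=int)
        xmin, ymin = xy.min(axis=0) - halo_um
        xmax, ymax = xy.max(axis=0) + halo_um
        ax = np.arange(xmin + pixel_um / 2, xmax, pixel_um)
        ay = np.arange(ymin + pixel_um / 2, ymax, pixel_um)
        if len(ax) == 0:
            ax = np.array([(xmin + xmax) / 2])
        if len(ay) == 0:
            ay = np.array([(ymin + ymax) / 2])
        gx, gy = np.meshgrid(ax, ay)
        pix = np.column_stack([gx.ravel(), gy.ravel()])
        dist, idx = cKDTree(xy).query(pix, k=1)
        covered = dist <= halo_um
        attributed = regions[idx[covered]]
        areas = pd.Series(attributed).value_counts() * px_mm2
        out[case_id] = areas.reindex(range(1, assignment.k + 1), fill_value=0.0)
    result = pd.DataFrame(out).T
    result.index.name = "case_id"
    result.columns.name = "region_id"
    return result


@dataclass
class RegionStats:
    """Tidy regional statistics for a cohort.

    Attributes
    ----------
    tidy
        One row per case × region × cell type: count, area_mm2, density
        (cells/mm²; NaN for zero-area regions).
    region_summary
        One row per case × region: cell count, percent of case cells,
        area, total-CD8 count and density (both T-cell subsets pooled).
    es_ratios
        One row per case × immune subset: epithelial-region density over
        stromal-region density (pseudo-density 0.5/area where a count is
        zero).  Empty unless the assignment carries compartment labels.
    """

    tidy: pd.DataFrame
    region_summary: pd.DataFrame
    es_ratios: pd.DataFrame

    def argmax_region(self, cell_type: str | None = None) -> pd.Series:
        """Per case, the region (by compartment name if labeled, else id)
        with the highest density of ``cell_type`` (default: total CD8)."""
        if cell_type is None:
            df = self.region_summary
            dens = df.set_index(["case_id", "region_id"])["cd8_total_density"]
        else:
            sub = self.tidy[self.tidy["cell_type"] == cell_type]
            dens = sub.set_index(["case_id", "region_id"])["density"]
        labels = self.region_summary.set_index(["case_id", "region_id"])["compartment"]
        out = {}
        for case_id in dens.index.get_level_values(0).unique():
            d = dens.loc[case_id].dropna()
            if d.empty:
                out[case_id] = None
                continue
            rid = int(d.idxmax())
            name = labels.loc[(case_id, rid)]
            out[case_id] = name if name else rid
        return pd.Series(out, name="argmax_region")


def densities_and_ratios(
    assignment: RegionAssignment, table: CellTable, areas: pd.DataFrame
) -> RegionStats:
    """Per-region counts, densities, total-CD8 density and E:S ratios.

    ``areas`` must come from :func:`estimate_region_area` under the same
    assignment.  Densities for empty (zero-area) regions are NaN.  The
    epithelial:stromal ratio per immune subset divides the subset's
    density in the epithelial-labeled region by that in the
    stromal-labeled region, substituting a pseudo-density of half a cell
    per region area when either count is zero.
    """
    df = _merged(assignment, table)
    types = list(table.cell_types)
    region_ids = list(range(1, assignment.k + 1))
    comp_of = (
        df.drop_duplicates(["case_id", "region_id"])
        .set_index(["case_id", "region_id"])["compartment"]
        .to_dict()
    )

    tidy_rows, summary_rows = [], []
    for case_id, sub in df.groupby("case_id", sort=False):
        counts = (
            sub.groupby(["region_id", "phenotype"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=region_ids, columns=types, fill_value=0)
        )
        for rid in region_ids:
            area = float(areas.loc[case_id, rid])
            comp = comp_of.get((case_id, rid), "")
            for t in types:
                c = int(counts.loc[rid, t])
                tidy_rows.append(
                    {
                        "case_id": case_id,
                        "region_id": rid,
                        "compartment": comp,
                        "cell_type": t,
                        "count": c,
                        "area_mm2": area,
                        "density": c / area if area > 0 else np.nan,
                    }
                )
            n_cells = int(counts.loc[rid].sum())
            cd8 = int(counts.loc[rid, T_NEG] + counts.loc[rid, T_POS])
            summary_rows.append(
                {
                    "case_id": case_id,
                    "region_id": rid,
                    "compartment": comp,
                    "n_cells": n_cells,
                    "percent_of_cells": 100.0 * n_cells / len(sub),
                    "area_mm2": area,
                    "cd8_total_count": cd8,
                    "cd8_total_density": cd8 / area if area > 0 else np.nan,
                }
            )
    tidy = pd.DataFrame(tidy_rows)
    summary = pd.DataFrame(summary_rows)

    ratio_rows = []
    labeled = summary[summary["compartment"].isin(["epithelial", "stromal"])]
    if not labeled.empty:
        key = tidy.set_index(["case_id", "compartment", "cell_type"])
        for case_id in summary["case_id"].unique():
            for subset in IMMUNE_SUBSETS:
                try:
                    num = key.loc[(case_id, "epithelial", subset)]
                    den = key.loc[(case_id, "stromal", subset)]
                except KeyError:
                    continue
                if num["area_mm2"] <= 0 or den["area_mm2"] <= 0:
                    continue
                dn = num["count"] / num["area_mm2"] if num["count"] else 0.5 / num["area_mm2"]
                dd = den["count"] / den["area_mm2"] if den["count"] else 0.5 / den["area_mm2"]
                ratio_rows.append(
                    {"case_id": case_id, "subset": subset, "es_ratio": dn / dd}
                )
    es = pd.DataFrame(ratio_rows, columns=["case_id", "subset", "es_ratio"])
    return RegionStats(tidy=tidy, region_summary=summary, es_ratios=es)


def fold_change_matrix(
    assignment: RegionAssignment,
    profiles: NeighborhoodProfiles,
    pseudocount: float = FOLD_CHANGE_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold change of mean neighborhood abundance between region pairs.

    For cell type ``t`` and regions ``(r1, r2)``,
    ``FC = (mean count of t in r1 neighborhoods + c) / (same for r2 + c)``
    with pseudo-count ``c`` so the reciprocal symmetry
    ``FC(t; r1, r2) = 1 / FC(t; r2, r1)`` holds exactly even for immune-
    poor regions.  Pairs involving an empty region are NaN.
    """
    adf = assignment.df.set_index("cell_id")
    region = adf.loc[profiles.cell_ids, "region_id"].to_numpy(dtype=int)
    types = list(profiles.cell_types)
    region_ids = list(range(1, assignment.k + 1))
    means = {}
    for rid in region_ids:
        mask = region == rid
        means[rid] = profiles.counts[mask].mean(axis=0) if mask.any() else None
    rows = []
    for t_idx, t in enumerate(types):
        for r1 in region_ids:
            for r2 in region_ids:
                if r1 == r2:
                    continue
                if means[r1] is None or means[r2] is None:
                    fc = np.nan
                else:
                    fc = (means[r1][t_idx] + pseudocount) / (means[r2][t_idx] + pseudocount)
                rows.append(
                    {"cell_type": t, "region_1": r1, "region_2": r2, "fold_change": fc}
                )
    return pd.DataFrame(rows)
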