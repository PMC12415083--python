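"""Nearest-neighbor distance analysis between cell types.

Two complementary read-outs of T-cell infiltration:

* a per-cell *distance map* — for every epithelial cell, the Euclidean
  distance to its nearest CD8+TIM3- T cell in the same spot, which paints
  "hot" (close) and "cold" (100+ μm) tumor areas; and
* a cohort-level log–log regression of T-cell abundance (as % of total
  cells) on the per-case median of those distances, capturing that
  abundant infiltrates sit closer to tumor cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .io import DEFAULT_CELL_TYPES, CellTable

__all__ = ["DistanceMap", "AbundanceDistanceFit", "nearest_distance_map", "abundance_distance_fit"]


@dataclass
class DistanceMap:
    """Per-source-cell nearest-target distances.

    ``df`` has one row per source cell: cell_id, case_id, x_um, y_um,
    distance_um (NaN where the case has no target cells) and a boolean
    ``defined`` flag distinguishing a true NaN-free measurement.
    """

    df: pd.DataFrame
    source_type: str
    target_type: str

    def case_medians(self) -> pd.Series:
        """Median distance per case over defined entries; NaN if none."""
        return self.df.groupby("case_id", sort=False).apply(
            lambda g: float(np.median(g.loc[g["defined"], "distance_um"]))
            if g["defined"].any()
            else np.nan,
            include_groups=False,
        )


@dataclass
class AbundanceDistanceFit:
    """OLS fit of log10(target % of cells) on log10(median distance)."""

    per_case: pd.DataFrame  # case_id, target_fraction_pct, median_distance_um
    slope: float
    intercept: float
    r_squared: float

    def predict_pct(self, median_distance_um: np.ndarray) -> np.ndarray:
        return 10 ** (self.intercept + self.slope * np.log10(median_distance_um))


def nearest_distance_map(
    table: CellTable,
    source_type: str = "epithelial",
    target_type: str = DEFAULT_CELL_TYPES[0],
) -> DistanceMap:
    """Exact distance from each source cell to its nearest target cell.

    Distances are computed within each case only — spots are disjoint
    tissues, so cross-spot neighbors are meaningless.  Cases without any
    target cell get flagged-undefined (NaN) distances rather than a cap.
    """
    source_type = table.cell_types.canonical(source_type)
    target_type = table.cell_types.canonical(target_type)
    rows = []
    for case_id in table.case_ids:
        sub = table.df[table.df["case_id"] == case_id]
        src = sub[sub["phenotype"] == source_type]
        tgt = sub[sub["phenotype"] == target_type]
        if len(src) == 0:
            continue
        if len(tgt) == 0:
            dist = np.full(len(src), np.nan)
        else:
            tree = cKDTree(tgt[["x_um", "y_um"]].to_numpy(dtype=float))
            dist, _ = tree.query(src[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": src["cell_id"].to_numpy(),
                    "case_id": case_id,
                    "x_um": src["x_um"].to_numpy(),
                    "y_um": src["y_um"].to_numpy(),
                    "distance_um": dist,
                    "defined": np.isfinite(dist),
                }
            )
        )
    if not rows:
        warnings.warn(
            f"no {source_type!r} cells in any case; distance map is empty",
            stacklevel=2,
        )
        df = pd.DataFrame(
            columns=["cell_id", "case_id", "x_um", "y_um", "distance_um", "defined"]
        )
    else:
        df = pd.concat(rows, ignore_index=True)
    return DistanceMap(df=df, source_type=source_type, target_type=target_type)


def abundance_distance_fit(dmap: DistanceMap, table: CellTable) -> AbundanceDistanceFit:
    """Regress log10 target abundance on log10 median nearest distance.

    Target abundance per case is the target-cell count as a percentage of
    *all* cells (artifact objects included in the denominator, since they
    are retained throughout the analysis).  Cases whose median distance is
    undefined (no target or no source cells) are excluded; at least three
    eligible cases are required.
    """
    medians = dmap.case_medians()
    counts = table.df.groupby("case_id", sort=False)["phenotype"].agg(
        total="size", target=lambda s: int((s == dmap.target_type).sum())
    )
    rows = []
    for case_id, med in medians.items():
        if not np.isfinite(med):
            continue
        total = counts.loc[case_id, "total"]
        target = counts.loc[case_id, "target"]
        if target == 0:
            continue
        rows.append(
            {
                "case_id": case_id,
                "target_fraction_pct": 100.0 * target / total,
                "median_distance_um": med,
            }
        )
    per_case = pd.DataFrame(rows)
    if len(per_case) < 3:
        raise ValueError(
            f"abundance–distance fit needs >= 3 eligible cases, got {len(per_case)}"
        )
    res = sps.linregress(
        np.log10(per_case["median_distance_um"]),
        np.log10(per_case["target_fraction_pct"]),
    )
    return AbundanceDistanceFit(
        per_case=per_case,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
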