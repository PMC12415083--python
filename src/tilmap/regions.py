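"""Region clustering of neighborhood profiles and compartment labeling.

Neighborhood composition vectors from all cases are pooled and clustered
with k-means (squared-Euclidean objective, multiple seeded restarts) into
a user-specified number of regions, so region identities are shared
across the cohort.  Every cell is then assigned to its nearest region
centroid.  For k = 2 or 3 the regions are given semantic compartment
names from their mean epithelial/stromal composition: the
epithelial-richest region is "epithelial", the stromal-richest "stromal",
and (k = 3) the remaining intermediate-composition region is the
epithelial–stromal "interface".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import CellTypeSet
from .neighborhood import NeighborhoodProfiles, WeightConfig

__all__ = ["RegionModel", "RegionAssignment", "fit_regions", "assign_regions", "label_compartments"]

MAX_REGIONS = 15


class FitError(RuntimeError):
    pass


class LabelingError(RuntimeError):
    """The clustering is too degenerate to name compartments."""


@dataclass
class RegionModel:
    """A fitted region clustering.

    ``centroids`` live in weighted-profile space (the clustering feature
    space); ``mean_composition`` is the per-region mean of *unweighted*
    composition fractions, which is what the semantic labels are read
    from.  Regions are numbered 1..k in order of decreasing mean
    epithelial fraction, so region 1 is always the most epithelial.
    """

    k: int
    centroids: np.ndarray  # (k, n_types), weighted space
    config: WeightConfig
    cell_types: CellTypeSet
    mean_composition: np.ndarray  # (k, n_types), unweighted fractions
    seed: int
    inertia: float
    compartments: dict[int, str] | None = None  # region_id -> name

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, self.k + 1))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "k": self.k,
            "centroids": self.centroids.tolist(),
            "mean_composition": self.mean_composition.tolist(),
            "cell_types": list(self.cell_types),
            "radius_um": self.config.radius_um,
            "weights": self.config.weights,
            "use_fractions": self.config.use_fractions,
            "seed": self.seed,
            "inertia": self.inertia,
            "compartments": self.compartments,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionModel":
        d = json.loads(Path(path).read_text())
        comp = d["compartments"]
        return cls(
            k=d["k"],
            centroids=np.asarray(d["centroids"], dtype=float),
            config=WeightConfig(
                radius_um=d["radius_um"],
                weights=d["weights"],
                use_fractions=d["use_fractions"],
            ),
            cell_types=CellTypeSet(tuple(d["cell_types"])),
            mean_composition=np.asarray(d["mean_composition"], dtype=float),
            seed=d["seed"],
            inertia=d["inertia"],
            compartments={int(k): v for k, v in comp.items()} if comp else None,
        )


@dataclass
class RegionAssignment:
    """Per-cell region membership (and compartment name where labeled)."""

    df: pd.DataFrame  # cell_id, case_id, region_id, compartment
    k: int

    def region_of(self) -> pd.Series:
        return self.df.set_index("cell_id")["region_id"]


def _nearest_centroid(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of nearest centroid per row; ties go to the lowest index."""
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin returns first (lowest) on ties


def fit_regions(
    profiles: NeighborhoodProfiles,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> RegionModel:
    """Cluster pooled weighted profiles into ``k`` regions.

    k-means with ``n_restarts`` deterministically seeded restarts; the
    run with the lowest within-cluster sum of squares is kept.  Regions
    are renumbered by decreasing mean epithelial composition so that
    region identity is stable across reruns.
    """
    if not 1 <= k <= MAX_REGIONS:
        raise FitError(f"k must be in 1..{MAX_REGIONS}, got {k}")
    X = profiles.weighted
    if len(X) < k:
        raise FitError(f"need at least k={k} profiles, got {len(X)}")

    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed,
        max_iter=300,
        tol=1e-6,
        algorithm="lloyd",
    ).fit(X)
    centroids = km.cluster_centers_
    labels = _nearest_centroid(X, centroids)
    if len(np.unique(labels)) < k:
        raise FitError(
            f"degenerate clustering: only {len(np.unique(labels))} of {k} "
            "regions are nonempty after all restarts"
        )

    fractions = profiles.fractions
    mean_comp = np.vstack([fractions[labels == j].mean(axis=0) for j in range(k)])

    # stable region numbering: decreasing epithelial fraction
    epi_col = profiles.cell_types.index("epithelial")
    order = np.argsort(-mean_comp[:, epi_col], kind="stable")
    return RegionModel(
        k=k,
        centroids=centroids[order],
        config=profiles.config,
        cell_types=profiles.cell_types,
        mean_composition=mean_comp[order],
        seed=seed,
        inertia=float(km.inertia_),
    )


def assign_regions(model: RegionModel, profiles: NeighborhoodProfiles) -> RegionAssignment:
    """Assign every cell to its nearest region centroid (weighted space).

    Ties break toward the lowest region id.  Profiles must have been
    computed with the model's radius/weight configuration.
    """
    if profiles.config != model.config:
        raise ValueError(
            "profiles were computed with a different neighborhood configuration "
            f"({profiles.config} != {model.config})"
        )
    X = profiles.weighted
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"profile dimension {X.shape[1]} != centroid dimension "
            f"{model.centroids.shape[1]}"
        )
    region_id = _nearest_centroid(X, model.centroids) + 1
    comp = (
        np.array([model.compartments.get(r, "") for r in region_id], dtype=object)
        if model.compartments
        else np.full(len(region_id), "", dtype=object)
    )
    df = pd.DataFrame(
        {
            "cell_id": profiles.cell_ids,
            "case_id": profiles.case_ids,
            "region_id": region_id,
            "compartment": comp,
        }
    )
    return RegionAssignment(df=df, k=model.k)


def label_compartments(model: RegionModel) -> RegionModel:
    """Name regions from their epithelial/stromal mean composition.

    Only the epithelial and stromal fractions enter (renormalized to sum
    to 1): immune and artifact dimensions are excluded because the
    interface is defined purely by epithelial/stromal abundance — a
    region with roughly equal amounts of both.  Requires k in {2, 3};
    mutates nothing, returns a labeled copy.
    """
    if model.k not in (2, 3):
        raise LabelingError(f"compartment labeling requires k in {{2, 3}}, got k={model.k}")
    epi = model.cell_types.index("epithelial")
    str_ = model.cell_types.index("stromal")
    pair = model.mean_composition[:, [epi, str_]]
    denom = pair.sum(axis=1)
    if np.any(denom == 0):
        raise LabelingError("a region has no epithelial or stromal content")
    epi_frac = pair[:, 0] / denom
    epi_region = int(np.argmax(epi_frac))
    str_region = int(np.argmax(1 - epi_frac))
    if epi_region == str_region:
        raise LabelingError("one region maximizes both epithelial and stromal fractions")
    labels = {epi_region + 1: "epithelial", str_region + 1: "stromal"}
    if model.k == 3:
        (mid,) = set(range(model.k)) - {epi_region, str_region}
        labels[mid + 1] = "interface"
    return RegionModel(
        k=model.k,
        centroids=model.centroids,
        config=model.config,
        cell_types=model.cell_types,
        mean_composition=model.mean_composition,
        seed=model.seed,
        inertia=model.inertia,
        compartments=labels,
    )
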