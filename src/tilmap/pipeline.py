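"""End-to-end orchestration: simulate/load → profiles → cluster → stats.

A run takes either real cell tables (CSV) or a synthetic-cohort
configuration, computes neighborhood profiles once, clusters them at each
requested region count (default 8, 3 and 2 — the exploratory model and
the three-/two-compartment models), writes every stage's tables, and a
manifest with parameters and content hashes so identical configurations
can be verified to reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .distance import abundance_distance_fit, nearest_distance_map
from .io import DEFAULT_CELL_TYPES, CellTable, read_cells, write_cells, write_cells_with_regions
from .neighborhood import WeightConfig, compute_profiles
from .regions import fit_regions, assign_regions, label_compartments
from .stats import densities_and_ratios, estimate_region_area, fold_change_matrix, region_percentages
from .synthetic import SimConfig, simulate_case

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("tilmap")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``cells_csv`` (existing table) or ``sim`` (synthetic
    cohort) must be given.  ``k_list`` selects the region counts to fit;
    compartment labeling is applied automatically for k in {2, 3}.
    """

    out_dir: Path
    cells_csv: str | Path | list[str | Path] | None = None
    sim: SimConfig | None = None
    weight_config: WeightConfig = field(default_factory=WeightConfig)
    k_list: tuple[int, ...] = (8, 3, 2)
    seed: int = 0
    distance_source: str = "epithelial"
    distance_target: str = DEFAULT_CELL_TYPES[0]
    make_figures: bool = False

    def __post_init__(self) -> None:
        if (self.cells_csv is None) == (self.sim is None):
            raise ValueError("exactly one of cells_csv or sim must be set")
        if any(not 1 <= k <= 15 for k in self.k_list):
            raise ValueError("k values must be within 1..15")
        self.out_dir = Path(self.out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict] = {}

    def record(path: Path, stage: str, **params) -> None:
        outputs[str(path.relative_to(out))] = {
            "stage": stage,
            "sha256": _sha256(path),
            **params,
        }

    # --- input stage -----------------------------------------------------
    if config.sim is not None:
        log.info("simulating %d cases", config.sim.n_cases)
        tables = []
        for i in range(config.sim.n_cases):
            case = simulate_case(config.sim, i)
            tables.append(case.table)
            case_id = case.table.case_ids[0]
            p = write_cells(case.table, out / "cells" / f"{case_id}.csv")
            record(p, "simulate", case_id=case_id, seed=config.sim.seed, case_index=i)
            tp = out / "cells" / f"{case_id}_truth.csv"
            case.truth.df.to_csv(tp, index=False)
            record(tp, "simulate", case_id=case_id)
            log.info("  %s: %d cells", case_id, len(case.table))
        table = CellTable(
            pd.concat([t.df for t in tables], ignore_index=True), tables[0].cell_types
        )
    else:
        log.info("reading cells from %s", config.cells_csv)
        table = read_cells(config.cells_csv)

    # --- neighborhood profiles ------------------------------------------
    log.info("computing neighborhood profiles (radius %.1f μm)", config.weight_config.radius_um)
    profiles = compute_profiles(table, config.weight_config)
    pp = out / "profiles.csv"
    profiles.to_frame().to_csv(pp, index=False)
    record(pp, "profile", radius_um=config.weight_config.radius_um)

    # --- region models ---------------------------------------------------
    for k in config.k_list:
        log.info("clustering k=%d", k)
        model = fit_regions(profiles, k=k, seed=config.seed)
        if k in (2, 3):
            model = label_compartments(model)
        assignment = assign_regions(model, profiles)

        mp = model.to_json(out / f"model_k{k}.json")
        record(mp, "cluster", k=k, seed=config.seed)
        ap = out / f"cells_regions_k{k}.csv"
        write_cells_with_regions(table, assignment, ap)
        record(ap, "cluster", k=k)

        pct = region_percentages(assignment, table)
        pctp = out / f"region_percentages_k{k}.csv"
        pct.to_csv(pctp)
        record(pctp, "stats", k=k)

        areas = estimate_region_area(assignment, table)
        rstats = densities_and_ratios(assignment, table, areas)
        sp = out / f"region_stats_k{k}.csv"
        rstats.tidy.to_csv(sp, index=False)
        record(sp, "stats", k=k)
        fc = fold_change_matrix(assignment, profiles)
        fcp = out / f"fold_changes_k{k}.csv"
        fc.to_csv(fcp, index=False)
        record(fcp, "stats", k=k)

        summary = {
            "k": k,
            "compartments": model.compartments,
            "cd8_argmax_region": {
                str(c): v for c, v in rstats.argmax_region().items()
            },
            "es_ratios": rstats.es_ratios.to_dict(orient="records"),
        }
        sj = out / f"summary_k{k}.json"
        sj.write_text(json.dumps(summary, indent=2, default=str))
        record(sj, "stats", k=k)

        if config.make_figures:
            from . import plotting

            for case_id in table.case_ids:
                fig = plotting.plot_region_map(assignment, table, case_id)
                fig.savefig(out / f"region_map_k{k}_{case_id}.png", dpi=150)
                import matplotlib.pyplot as plt

                plt.close(fig)

    # --- distance analysis ----------------------------------------------
    log.info("distance analysis %s → %s", config.distance_source, config.distance_target)
    dmap = nearest_distance_map(table, config.distance_source, config.distance_target)
    dp = out / "distance_map.csv"
    dmap.df.to_csv(dp, index=False)
    record(dp, "distance")
    try:
        fit = abundance_distance_fit(dmap, table)
        fj = out / "distance_fit.json"
        fj.write_text(
            json.dumps(
                {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "per_case": fit.per_case.to_dict(orient="records"),
                },
                indent=2,
            )
        )
        record(fj, "distance")
        if config.make_figures:
            from . import plotting
            import matplotlib.pyplot as plt

            fig = plotting.plot_abundance_distance(fit)
            fig.savefig(out / "distance_fit.png", dpi=150)
            plt.close(fig)
    except ValueError as e:  # fewer than 3 eligible cases
        log.warning("abundance–distance fit skipped: %s", e)

    manifest = {
        "tilmap_version": __version__,
        "seed": config.seed,
        "k_list": list(config.k_list),
        "weight_config": {
            "radius_um": config.weight_config.radius_um,
            "weights": config.weight_config.weights,
            "use_fractions": config.weight_config.use_fractions,
        },
        "n_cases": len(table.case_ids),
        "n_cells": len(table),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
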