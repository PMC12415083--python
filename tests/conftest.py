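import numpy as np
import pandas as pd
import pytest

import tilmap as tm

T_NEG, T_POS, MACRO, EPI, STROMA, SMUDGE = tm.DEFAULT_CELL_TYPES


def random_table(rng: np.random.Generator, n: int, extent: float = 800.0) -> tm.CellTable:
    """Uniform random cells with random phenotypes, two cases."""
    df = pd.DataFrame(
        {
            "case_id": rng.choice(["A", "B"], size=n),
            "cell_id": [f"r{i}" for i in range(n)],
            "x_um": rng.uniform(0, extent, size=n),
            "y_um": rng.uniform(0, extent, size=n),
            "phenotype": rng.choice(list(tm.DEFAULT_CELL_TYPES), size=n),
        }
    )
    return tm.CellTable(df)


def pooled(cases) -> tm.CellTable:
    return tm.CellTable(
        pd.concat([c.table.df for c in cases], ignore_index=True),
        cases[0].table.cell_types,
    )


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic cohort, reused across tests."""
    return tm.default_scenario(seed=0)


@pytest.fixture(scope="session")
def scenario_table(scenario):
    return pooled(scenario)


@pytest.fixture(scope="session")
def scenario_profiles(scenario_table):
    return tm.compute_profiles(scenario_table)


@pytest.fixture(scope="session")
def scenario_k3(scenario_table, scenario_profiles):
    model = tm.label_compartments(tm.fit_regions(scenario_profiles, 3, seed=0))
    assignment = tm.assign_regions(model, scenario_profiles)
    return model, assignment


@pytest.fixture(scope="session")
def cohort_sweep():
    """Per-seed pipeline summaries on the default scenario, seeds 0–9.

    Computed once and shared by the acceptance tests: compartment-recovery
    ARI, top-CD8-density compartment per case under the three- and
    two-compartment models, E:S subset-ratio ordering, and the
    abundance–distance fit.
    """
    from sklearn.metrics import adjusted_rand_score

    out = []
    for seed in range(10):
        cases = tm.default_scenario(seed=seed)
        table = pooled(cases)
        profiles = tm.compute_profiles(table)
        res = {"seed": seed, "n_cases": len(cases)}
        models = {}
        for k in (3, 2):
            model = tm.label_compartments(tm.fit_regions(profiles, k, seed=0))
            assignment = tm.assign_regions(model, profiles)
            areas = tm.estimate_region_area(assignment, table)
            stats = tm.densities_and_ratios(assignment, table, areas)
            models[k] = (model, assignment, stats)
        truth = np.concatenate(
            [c.truth.df["true_compartment"].to_numpy() for c in cases]
        )
        res["ari"] = adjusted_rand_score(
            truth, models[3][1].df["compartment"].to_numpy()
        )
        res["argmax_k3"] = models[3][2].argmax_region()
        res["argmax_k2"] = models[2][2].argmax_region()
        es = models[2][2].es_ratios.pivot(
            index="case_id", columns="subset", values="es_ratio"
        )
        res["es_order"] = (es[T_POS] > es[T_NEG]).to_numpy()
        fit = tm.abundance_distance_fit(tm.nearest_distance_map(table), table)
        res["slope"] = fit.slope
        res["r_squared"] = fit.r_squared
        out.append(res)
    return out
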