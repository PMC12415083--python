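import numpy as np
import pandas as pd
import pytest

import tilmap as tm
from tilmap.neighborhood import NeighborhoodProfiles, WeightConfig
from tilmap.regions import FitError, LabelingError, fit_regions

from conftest import EPI, STROMA, T_NEG


def profiles_from_counts(counts, config=None):
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    return NeighborhoodProfiles(
        cell_ids=np.array([f"c{i}" for i in range(n)]),
        case_ids=np.array(["A"] * n),
        counts=counts,
        cell_types=tm.CellTypeSet(),
        config=config or WeightConfig(),
    )


def make_model(mean_comp, k):
    types = tm.CellTypeSet()
    mc = np.asarray(mean_comp, dtype=float)
    return tm.RegionModel(
        k=k,
        centroids=mc.copy(),
        config=WeightConfig(),
        cell_types=types,
        mean_composition=mc,
        seed=0,
        inertia=0.0,
    )


class TestFitRegions:
    def test_k1_puts_every_cell_in_one_region(self, scenario_profiles):
        model = fit_regions(scenario_profiles, k=1, seed=0)
        assignment = tm.assign_regions(model, scenario_profiles)
        assert set(assignment.df["region_id"]) == {1}

    def test_separable_compositions_recover_the_dichotomy(self):
        """Pure-epithelial vs pure-stromal profiles split exactly at k=2."""
        types = tm.CellTypeSet()
        epi_row = np.zeros(len(types), dtype=int)
        epi_row[types.index(EPI)] = 5
        str_row = np.zeros(len(types), dtype=int)
        str_row[types.index(STROMA)] = 7
        counts = [epi_row] * 40 + [str_row] * 60
        prof = profiles_from_counts(counts)
        model = fit_regions(prof, k=2, seed=0)
        assignment = tm.assign_regions(model, prof)
        regions = assignment.df["region_id"].to_numpy()
        assert len(set(regions[:40])) == 1
        assert len(set(regions[40:])) == 1
        assert regions[0] != regions[-1]
        # region 1 is the epithelial-richer one by construction
        assert regions[0] == 1

    def test_k8_on_scenario_gives_eight_nonempty_regions(self, scenario_profiles):
        model = fit_regions(scenario_profiles, k=8, seed=0)
        assignment = tm.assign_regions(model, scenario_profiles)
        assert sorted(set(assignment.df["region_id"])) == list(range(1, 9))

    def test_deterministic_under_seed(self, scenario_profiles):
        a = fit_regions(scenario_profiles, k=3, seed=0)
        b = fit_regions(scenario_profiles, k=3, seed=0)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.mean_composition, b.mean_composition)

    def test_errors(self, scenario_profiles):
        with pytest.raises(FitError, match="k must be"):
            fit_regions(scenario_profiles, k=16)
        prof = profiles_from_counts([[1, 0, 0, 0, 0, 0]] * 2)
        with pytest.raises(FitError, match="at least k"):
            fit_regions(prof, k=3)

    def test_json_round_trip(self, tmp_path, scenario_profiles):
        model = tm.label_compartments(fit_regions(scenario_profiles, k=3, seed=0))
        p = model.to_json(tmp_path / "model.json")
        back = tm.RegionModel.from_json(p)
        assert np.array_equal(back.centroids, model.centroids)
        assert back.compartments == model.compartments
        assert back.config == model.config


class TestAssignRegions:
    def test_profile_equal_to_centroid_goes_to_that_region(self, scenario_profiles):
        model = fit_regions(scenario_profiles, k=3, seed=0)
        X = scenario_profiles.weighted
        d2 = ((X[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        assignment = tm.assign_regions(model, scenario_profiles)
        assert np.array_equal(
            assignment.df["region_id"].to_numpy(), d2.argmin(axis=1) + 1
        )

    def test_equidistant_tie_breaks_to_lowest_region(self):
        types = tm.CellTypeSet()
        model = make_model(np.eye(len(types))[:2], k=2)
        # profile equidistant from both centroids
        counts = np.ones((1, len(types)), dtype=int)
        prof = profiles_from_counts(counts)
        # craft weighted == fractions by unit weights
        prof.config = WeightConfig(weights={t: 1.0 for t in types})
        model.config = prof.config
        assignment = tm.assign_regions(model, prof)
        assert assignment.df["region_id"].tolist() == [1]

    def test_reassignment_reproduces_training_partition(self, scenario_profiles):
        """Mean region compositions recomputed from the assignment match the
        model, i.e. assignment is self-consistent with the fit."""
        model = fit_regions(scenario_profiles, k=3, seed=0)
        assignment = tm.assign_regions(model, scenario_profiles)
        frac = scenario_profiles.fractions
        for rid in model.region_ids:
            mask = (assignment.df["region_id"] == rid).to_numpy()
            assert np.allclose(
                frac[mask].mean(axis=0), model.mean_composition[rid - 1]
            )

    def test_config_mismatch_is_an_error(self, scenario_profiles):
        model = fit_regions(scenario_profiles, k=2, seed=0)
        other = tm.compute_profiles(
            tm.CellTable(
                pd.DataFrame(
                    {
                        "case_id": ["A"],
                        "cell_id": ["c"],
                        "x_um": [0.0],
                        "y_um": [0.0],
                        "phenotype": [EPI],
                    }
                )
            ),
            WeightConfig(radius_um=50.0),
        )
        with pytest.raises(ValueError, match="configuration"):
            tm.assign_regions(model, other)


class TestLabelCompartments:
    def test_three_region_forced_ordering(self):
        # epithelial/stromal fractions 0.9/0.1, 0.1/0.9, 0.5/0.5
        comp = np.zeros((3, 6))
        comp[:, 3] = [0.9, 0.5, 0.1]  # epithelial column (canonical order)
        comp[:, 4] = [0.1, 0.5, 0.9]  # stromal column
        model = tm.label_compartments(make_model(comp, k=3))
        assert model.compartments == {1: "epithelial", 2: "interface", 3: "stromal"}

    def test_two_region_forced_ordering(self):
        comp = np.zeros((2, 6))
        comp[:, 3] = [0.8, 0.2]
        comp[:, 4] = [0.2, 0.8]
        model = tm.label_compartments(make_model(comp, k=2))
        assert model.compartments == {1: "epithelial", 2: "stromal"}

    def test_degenerate_labeling_is_an_error(self):
        comp = np.zeros((2, 6))
        comp[:, 3] = [0.5, 0.5]
        comp[:, 4] = [0.5, 0.5]
        with pytest.raises(LabelingError):
            tm.label_compartments(make_model(comp, k=2))

    def test_k_outside_two_three_rejected(self, scenario_profiles):
        model = fit_regions(scenario_profiles, k=4, seed=0)
        with pytest.raises(LabelingError, match="k in"):
            tm.label_compartments(model)

    def test_interface_has_intermediate_epithelial_fraction(self, scenario_k3):
        model, _ = scenario_k3
        epi = model.cell_types.index(EPI)
        by_name = {v: model.mean_composition[k - 1, epi] for k, v in model.compartments.items()}
        assert by_name["stromal"] < by_name["interface"] < by_name["epithelial"]
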