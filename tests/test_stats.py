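import numpy as np
import pandas as pd
import pytest

import tilmap as tm
from tilmap.neighborhood import NeighborhoodProfiles, WeightConfig

from conftest import EPI, STROMA, T_NEG, T_POS


def assignment_from(cell_ids, case_ids, region_ids, k, compartments=None):
    comp = [""] * len(cell_ids)
    if compartments:
        comp = [compartments.get(r, "") for r in region_ids]
    return tm.RegionAssignment(
        df=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "case_id": case_ids,
                "region_id": region_ids,
                "compartment": comp,
            }
        ),
        k=k,
    )


def grid_table(case_id, origin, n_side, spacing, phenotype, prefix):
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    return pd.DataFrame(
        {
            "case_id": case_id,
            "cell_id": [f"{prefix}{i}" for i in range(n_side**2)],
            "x_um": origin[0] + xs.ravel() * spacing,
            "y_um": origin[1] + ys.ravel() * spacing,
            "phenotype": phenotype,
        }
    )


class TestRegionPercentages:
    def test_single_region_is_100(self):
        df = grid_table("A", (0, 0), 3, 10.0, EPI, "a")
        table = tm.CellTable(df)
        a = assignment_from(df["cell_id"], df["case_id"], [1] * len(df), k=1)
        pct = tm.region_percentages(a, table)
        assert pct.loc["A", 1] == 100.0

    def test_30_70_split(self):
        df = grid_table("A", (0, 0), 10, 10.0, EPI, "a")
        table = tm.CellTable(df)
        regions = [1] * 30 + [2] * 70
        a = assignment_from(df["cell_id"], df["case_id"], regions, k=2)
        pct = tm.region_percentages(a, table)
        assert pct.loc["A", 1] == pytest.approx(30.0)
        assert pct.loc["A", 2] == pytest.approx(70.0)

    def test_sums_to_100_on_scenario(self, scenario_table, scenario_k3):
        _, assignment = scenario_k3
        pct = tm.region_percentages(assignment, scenario_table)
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)


class TestRegionArea:
    def test_single_cell_halo_disk(self):
        df = grid_table("A", (100, 100), 1, 1.0, EPI, "a")
        table = tm.CellTable(df)
        a = assignment_from(df["cell_id"], df["case_id"], [1], k=1)
        areas = tm.estimate_region_area(a, table, pixel_um=5.0, halo_um=15.0)
        est_um2 = areas.loc["A", 1] * 1e6
        disk = np.pi * 15.0**2
        ring = 2 * np.pi * 15.0 * 5.0  # one pixel ring of tolerance
        assert abs(est_um2 - disk) <= ring

    def test_equal_planted_areas_agree_within_10pct(self):
        # two identical, well-separated cell grids, one region each
        df1 = grid_table("A", (0, 0), 20, 10.0, EPI, "a")
        df2 = grid_table("A", (1000, 0), 20, 10.0, STROMA, "b")
        df = pd.concat([df1, df2], ignore_index=True)
        table = tm.CellTable(df)
        regions = [1] * len(df1) + [2] * len(df2)
        a = assignment_from(df["cell_id"], df["case_id"], regions, k=2)
        areas = tm.estimate_region_area(a, table)
        assert abs(areas.loc["A", 1] - areas.loc["A", 2]) / areas.loc["A", 2] < 0.10

    def test_empty_region_has_zero_area_and_undefined_density(self):
        df = grid_table("A", (0, 0), 3, 10.0, EPI, "a")
        table = tm.CellTable(df)
        a = assignment_from(df["cell_id"], df["case_id"], [1] * len(df), k=2)
        areas = tm.estimate_region_area(a, table)
        assert areas.loc["A", 2] == 0.0
        stats = tm.densities_and_ratios(a, table, areas)
        empty = stats.tidy[(stats.tidy["region_id"] == 2)]
        assert np.isnan(empty["density"]).all()


class TestDensitiesAndRatios:
    def test_density_arithmetic(self):
        df = grid_table("A", (0, 0), 5, 10.0, T_NEG, "t")  # 25 T cells
        table = tm.CellTable(df)
        a = assignment_from(df["cell_id"], df["case_id"], [1] * 25, k=1)
        areas = pd.DataFrame({1: [0.5]}, index=pd.Index(["A"], name="case_id"))
        stats = tm.densities_and_ratios(a, table, areas)
        row = stats.tidy[(stats.tidy["cell_type"] == T_NEG)].iloc[0]
        assert row["density"] == pytest.approx(25 / 0.5)
        zero = stats.tidy[(stats.tidy["cell_type"] == EPI)].iloc[0]
        assert zero["density"] == 0.0

    def test_density_times_area_conserves_counts(self, scenario_table, scenario_k3):
        _, assignment = scenario_k3
        areas = tm.estimate_region_area(assignment, scenario_table)
        stats = tm.densities_and_ratios(assignment, scenario_table, areas)
        t = stats.tidy.dropna(subset=["density"])
        recovered = (t["density"] * t["area_mm2"]).groupby(
            [t["case_id"], t["cell_type"]]
        ).sum()
        expected = scenario_table.df.groupby(["case_id", "phenotype"]).size()
        for (case, ct), val in recovered.items():
            assert val == pytest.approx(expected.get((case, ct), 0), rel=1e-9)

    def test_es_ratio_uses_pseudo_density_for_zero_counts(self):
        comp = {1: "epithelial", 2: "stromal"}
        df = pd.concat(
            [
                grid_table("A", (0, 0), 4, 10.0, EPI, "e"),
                grid_table("A", (500, 0), 4, 10.0, STROMA, "s"),
                grid_table("A", (500, 500), 2, 10.0, T_NEG, "t"),  # stromal side
            ],
            ignore_index=True,
        )
        regions = [1] * 16 + [2] * 16 + [2] * 4
        table = tm.CellTable(df)
        a = assignment_from(df["cell_id"], df["case_id"], regions, k=2, compartments=comp)
        areas = pd.DataFrame(
            {1: [0.2], 2: [0.4]}, index=pd.Index(["A"], name="case_id")
        )
        stats = tm.densities_and_ratios(a, table, areas)
        r = stats.es_ratios.set_index("subset")["es_ratio"]
        # T- has 0 cells in the epithelial region: numerator = 0.5/0.2
        assert r[T_NEG] == pytest.approx((0.5 / 0.2) / (4 / 0.4))
        # T+ absent everywhere: 0.5/0.2 over 0.5/0.4
        assert r[T_POS] == pytest.approx((0.5 / 0.2) / (0.5 / 0.4))


class TestFoldChanges:
    def _profiles(self, counts, regions, k):
        counts = np.asarray(counts, dtype=np.int64)
        n = len(counts)
        prof = NeighborhoodProfiles(
            cell_ids=np.array([f"c{i}" for i in range(n)]),
            case_ids=np.array(["A"] * n),
            counts=counts,
            cell_types=tm.CellTypeSet(),
            config=WeightConfig(),
        )
        a = assignment_from(prof.cell_ids, prof.case_ids, regions, k=k)
        return prof, a

    def test_identical_compositions_give_fc_one(self):
        prof, a = self._profiles([[2, 0, 0, 3, 0, 0]] * 6, [1, 1, 1, 2, 2, 2], k=2)
        fc = tm.fold_change_matrix(a, prof)
        assert np.allclose(fc["fold_change"], 1.0)

    def test_pseudocount_arithmetic(self):
        # region 1 mean T- neighborhood count 2.0, region 2 mean 0.5
        prof, a = self._profiles(
            [[2, 0, 0, 0, 0, 0]] * 2 + [[1, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0]],
            [1, 1, 2, 2],
            k=2,
        )
        fc = tm.fold_change_matrix(a, prof)
        row = fc[
            (fc["cell_type"] == T_NEG) & (fc["region_1"] == 1) & (fc["region_2"] == 2)
        ].iloc[0]
        assert row["fold_change"] == pytest.approx(2.01 / 0.51)

    def test_reciprocal_symmetry(self, scenario_profiles, scenario_k3):
        _, assignment = scenario_k3
        fc = tm.fold_change_matrix(assignment, scenario_profiles)
        m = fc.set_index(["cell_type", "region_1", "region_2"])["fold_change"]
        for (t, r1, r2), v in m.items():
            assert v * m[(t, r2, r1)] == pytest.approx(1.0, rel=1e-12)

    def test_empty_region_flagged_nan(self):
        prof, a = self._profiles([[1, 0, 0, 0, 0, 0]] * 4, [1, 1, 1, 1], k=2)
        fc = tm.fold_change_matrix(a, prof)
        assert np.isnan(fc["fold_change"]).all()
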