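"""Regional densities: where do CD8+ T cells actually sit?

Compares the three-compartment model (epithelial / interface / stromal)
with the conventional two-compartment dichotomy.  Under k=3 the interface
holds the highest total-CD8 density in essentially every case; under k=2
that signal is diluted into the stromal region.  Also computes the
epithelial:stromal density ratio per immune subset — higher for exhausted
(TIM3+) than for TIM3- CD8 T cells.
"""

import pandas as pd

import tilmap as tm

cases = tm.default_scenario(seed=0)
table = tm.CellTable(
    pd.concat([c.table.df for c in cases], ignore_index=True),
    cases[0].table.cell_types,
)
profiles = tm.compute_profiles(table)

for k in (3, 2):
    model = tm.label_compartments(tm.fit_regions(profiles, k, seed=0))
    assignment = tm.assign_regions(model, profiles)
    areas = tm.estimate_region_area(assignment, table)
    stats = tm.densities_and_ratios(assignment, table, areas)
    top = stats.argmax_region()
    print(f"k={k}: top total-CD8-density compartment per case:")
    print("  " + ", ".join(f"{c}:{v}" for c, v in top.items()))
    if k == 2:
        es = stats.es_ratios.pivot(index="case_id", columns="subset",
                                   values="es_ratio")
        es = es[["CD8+TIM3+ T cell", "CD8+TIM3- T cell"]]
        print("\nEpithelial:stromal density ratios (k=2 regions):")
        print(es.round(2).to_string())
        n = (es["CD8+TIM3+ T cell"] > es["CD8+TIM3- T cell"]).sum()
        print(f"\nES ratio higher for the exhausted subset in {n} of {len(es)} "
              "cases: TIM3+ CD8 T cells push relatively deeper into the epithelium.")
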