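"""Simulate a synthetic TMA cohort and inspect its planted structure.

Generates the default ten-spot cohort: each spot is a 1.2 mm tissue core
with epithelial tumor deposits, intervening stroma, a 30 μm-wide
epithelial–stromal interface band, and three immune populations whose
compartment preferences are planted (CD8+TIM3+ exhausted T cells lean
toward interface and epithelium; CD8+TIM3- T cells toward stroma and
interface).
"""

import tilmap as tm

cases = tm.default_scenario(seed=0)

print(f"{'case':<5} {'cells':>6} {'CD8+TIM3-':>10} {'CD8+TIM3+':>10} "
      f"{'%epi truth':>10} {'%int truth':>10}")
for case in cases:
    counts = case.table.type_counts()
    truth = case.truth.df["true_compartment"]
    print(
        f"{case.table.case_ids[0]:<5} {len(case.table):>6} "
        f"{counts['CD8+TIM3- T cell']:>10} {counts['CD8+TIM3+ T cell']:>10} "
        f"{100 * (truth == 'epithelial').mean():>10.1f} "
        f"{100 * (truth == 'interface').mean():>10.1f}"
    )

areas = cases[0].geometry.compartment_areas()
print("\nT1 compartment areas (mm²):",
      {k: round(v, 3) for k, v in areas.items()})
print("T-cell counts fall ~10-fold from T10 to T1: the cohort spans "
      "immune-poor to immune-rich tumors, as real cohorts do.")
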