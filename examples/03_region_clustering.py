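"""Neighborhood clustering: exploratory 8-region and 3-compartment models.

Each cell's neighborhood (radius 30 μm) is summarized as a weighted
composition vector (weights 8/8/5 up-weight the sparse immune types) and
the pooled vectors are k-means-clustered.  k=8 resolves immune-enriched
micro-regions; k=3 yields the epithelial / interface / stromal
compartment model, with compartments named from their epithelial vs
stromal content.
"""

import numpy as np
import pandas as pd

import tilmap as tm

cases = tm.default_scenario(seed=0)
table = tm.CellTable(
    pd.concat([c.table.df for c in cases], ignore_index=True),
    cases[0].table.cell_types,
)
profiles = tm.compute_profiles(table)  # radius 30 μm, weights 8/8/5/1/1/1

model8 = tm.fit_regions(profiles, k=8, seed=0)
print("k=8 mean region compositions (rows = regions, cols = cell types):")
print(pd.DataFrame(np.round(model8.mean_composition, 2),
                   index=[f"R{r}" for r in model8.region_ids],
                   columns=list(table.cell_types)).to_string())

model3 = tm.label_compartments(tm.fit_regions(profiles, k=3, seed=0))
assignment = tm.assign_regions(model3, profiles)
print("\nk=3 compartments:", model3.compartments)
print("k=3 mean epithelial fraction per region:",
      np.round(model3.mean_composition[:, table.cell_types.index('epithelial')], 2))

truth = np.concatenate([c.truth.df["true_compartment"].to_numpy() for c in cases])
from sklearn.metrics import adjusted_rand_score
ari = adjusted_rand_score(truth, assignment.df["compartment"].to_numpy())
print(f"\nAdjusted Rand index vs planted geometry: {ari:.2f}")
print("The interface compartment sits between the pure regions in "
      "epithelial content — the transitional zone the 2-compartment view misses.")
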