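# tilmap

Compartment mapping of tumor single-cell point patterns: partition each
tumor into **epithelial**, **stromal**, and **epithelial–stromal
interface** compartments by clustering cell-neighborhood composition, and
quantify where CD8+ T-cell subsets and TIM3+ macrophages actually reside.

## The problem

Tumor-infiltrating lymphocytes (TILs) are conventionally scored in a
two-compartment view of the tumor — epithelial nests versus stroma.  But
carcinomas such as high-grade serous ovarian cancer are built from
epithelial deposits separated by sub-millimeter bands of infiltrating
stroma, and much of the immune action concentrates in the narrow
transitional zone where the two meet.  A two-compartment read-out dilutes
that signal into "stroma".  `tilmap` takes phenotyped single-cell tables
(e.g. QuPath detection exports from multiplex immunofluorescence — one row
per cell with position in μm and one of six phenotypes: CD8+TIM3- T cell,
CD8+TIM3+ T cell, TIM3+CD8- macrophage, epithelial, stromal, artifact) and
maps the interface as a first-class compartment.

## The method

For each cell *i*, the **neighborhood profile** counts cells of each
phenotype *t* within radius *r* (default 30 μm, closed ball, cell itself
included):

```
n_i[t] = #{ j in same spot : ||x_j − x_i|| ≤ r, phenotype(j) = t }
f_i    = n_i / Σ_t n_i[t]                (composition fractions)
z_i    = f_i ∘ w                         (per-type weights, default 8/8/5/1/1/1)
```

The weights up-weight the sparse immune types so they can pull a
neighborhood away from the dominant epithelial/stromal axis.  The pooled
vectors `z_i` from all cases are clustered with k-means (squared-Euclidean
objective, seeded restarts) into a user-chosen number of regions *k*
(1–15): *k* = 8 for an exploratory atlas of immune micro-regions, *k* = 3
for the three-compartment model and *k* = 2 for the conventional
dichotomy.  For *k* ∈ {2, 3} regions are named from their mean
epithelial/stromal composition — the intermediate-composition region (≈
half epithelial, half stromal neighborhoods) is the **interface**.

Regional statistics follow: region percentages, region areas (nearest-cell
raster with a 15 μm halo), per-type densities in cells/mm², total-CD8
density per compartment, epithelial:stromal density ratios per immune
subset, and fold changes of mean neighborhood abundance between region
pairs.  A separate distance module computes, per epithelial cell, the
exact distance to its nearest CD8+TIM3- T cell, and regresses
log10(T-cell % of all cells) on log10(median distance) across cases.

A built-in synthetic TMA generator (`tilmap.synthetic`) plants known
compartment geometry (disk deposits, 30 μm interface band) and known
immune compartment preferences, so recovery of the planted answer is
testable end-to-end without imaging data.

## Worked example

```python
import pandas as pd, tilmap as tm

cases = tm.default_scenario(seed=0)          # 10 synthetic TMA spots
table = tm.CellTable(pd.concat([c.table.df for c in cases],
                               ignore_index=True))
profiles = tm.compute_profiles(table)        # radius 30 μm, weights 8/8/5/1/1/1
model = tm.label_compartments(tm.fit_regions(profiles, k=3, seed=0))
assignment = tm.assign_regions(model, profiles)
stats = tm.densities_and_ratios(assignment, table,
                                tm.estimate_region_area(assignment, table))
print(model.compartments)
print(stats.argmax_region().to_dict())
```

prints

```
{1: 'epithelial', 3: 'stromal', 2: 'interface'}
{'T1': 'interface', 'T2': 'interface', ..., 'T10': 'interface'}
```

i.e. the interface compartment carries the highest total-CD8 T-cell
density in all ten cases — while rerunning with `k=2` puts the maximum in
the stromal region, hiding the interface enrichment.  The distance module
on the same cohort (`examples/02_distance_analysis.py`) prints a log–log
slope of −2.33 with r² = 0.92: T-cell-poor tumors keep their epithelial
cells 100+ μm from the nearest T cell, T-cell-rich ones ~60 μm.

The `examples/` directory has one short script per capability
(simulation, distance analysis, clustering, regional statistics,
end-to-end run); a thin CLI mirrors the stages:

```
tilmap run --simulate --out scratch/run1          # end-to-end
tilmap cluster --cells cells.csv --k 3 --out out/ # single stage
```

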