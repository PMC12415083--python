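# Methods

## Input model

The unit of analysis is a cohort of tissue-microarray (TMA) spots, each a
table of phenotyped cells: case id, centroid position in μm (image
convention — origin top-left, y downward, continuous coordinates), and a
phenotype from a fixed ordered panel of six: CD8+TIM3- T cell, CD8+TIM3+
(exhausted) T cell, TIM3+CD8- macrophage, epithelial, stromal, and
artifact ("smudge").  Artifact objects are deliberately retained: they
count in every total-cell denominator and travel through clustering as
their own profile dimension, so artifact-contaminated areas surface as
their own regions instead of silently skewing the others.  They are
excluded only from compartment *naming* (below).  Phenotype strings are
matched case-insensitively after whitespace normalization; the panel's
order fixes the column order of every feature vector, centroid, and
serialized model.

Two CSV dialects are read: a combined table with a phenotype column
(QuPath-style headers like `Centroid X µm` / `Class` are accepted through
a schema map) and a per-type file set whose filename stems name the
phenotype.  Coordinates are serialized with `repr` and parsed with
correctly-rounded `float()`, so write → read round-trips are bit-stable —
a requirement for the manifest's byte-identical-rerun guarantee.

## Neighborhood profiles

For cell *i*, `counts[t]` is the number of phenotype-*t* cells within
radius `radius_um` of *i* (closed ball; boundary distance exactly equal to
the radius counts) in the same spot — never across spots, which are
disjoint tissues.  The cell counts itself, so every total ≥ 1 and isolated
cells have a defined one-hot composition.  Counts are converted to
fractions and multiplied by per-type weights.  Defaults: radius 30 μm
(about 2–3 cell diameters); weights 8 for both CD8 subsets, 5 for
macrophages, 1 otherwise, chosen to let rare immune types express
themselves against the structural background.  Weights multiply
*fractions*, not raw counts, so the feature is invariant to local cell
density and regions mean "composition", not "crowding"; a raw-counts mode
remains available behind `WeightConfig(use_fractions=False)` for
comparison.  Neighbor search uses a k-d tree per spot; an O(n²)
enumeration serves as the exactness oracle in the tests.

## Region models and compartment naming

Weighted profiles are pooled over all cases — region identities are
cohort-wide — and clustered by k-means (squared-Euclidean objective,
Lloyd's algorithm, 10 seeded restarts, tolerance 1e-6, ≤300 iterations;
the restart with the lowest within-cluster sum of squares wins).  k-means
was chosen over a self-organizing map because the contract is only "a
user-chosen number of regions" and k-means is deterministic under a seed
with far less machinery; equivalence of the two partitions is not claimed.
Every cell is assigned to its nearest centroid, ties to the lowest region
id.  Regions are renumbered by decreasing mean epithelial composition so
that numbering is stable across reruns.

For k ∈ {2, 3} regions get compartment names from their mean *unweighted*
composition restricted to the epithelial and stromal fractions
(renormalized; immune and artifact dimensions excluded, because the
interface concept is defined purely by epithelial/stromal abundance): the
epithelial-richest region is "epithelial", the stromal-richest "stromal",
and at k = 3 the remaining intermediate region is the "interface".  A
clustering in which one region wins both maxima is refused as degenerate.

## Regional statistics

Region percentage = cells in region / cells in case × 100.  Region areas
are estimated from the cells themselves (region membership is a property
of cells, not pixels): the case bounding box, padded by a 15 μm halo, is
rasterized at 5 μm; every pixel within 15 μm of at least one cell is
attributed to its nearest cell's region; area = pixel count × 25 μm².
The halo is half the neighborhood radius, so area tracks tissue extent
rather than convex hulls.  Pixel size 5 μm keeps the discretization error
of a single-cell region below one pixel ring (~2πrh); density
conservation — Σ_regions density × area = raw count — holds to floating
point exactly by construction.

Densities are per-case counts over areas (undefined for empty regions).
The headline read-out is total-CD8 density (both CD8 subsets pooled) per
compartment, and the compartment achieving its per-case maximum.  The
epithelial:stromal density ratio per immune subset substitutes a
pseudo-density of half a cell per region area when a count is zero, so
immune-poor cases yield finite, conservative ratios.  This ratio is
computed from the *two-compartment* model's regions: that is the
conventional epithelial/stromal dichotomy the ratio describes, and under
the three-compartment model the immune-weighted interface cluster absorbs
T-cell-rich neighborhoods from both flanks, leaving the pure regions with
pseudo-count-dominated subset counts that no longer reflect compartment
preference.  Fold changes between regions use mean neighborhood counts
with a 0.01 pseudo-count, making reciprocal symmetry FC(r1,r2)·FC(r2,r1)=1
exact.

Distance analysis: exact nearest-neighbor distance (k-d tree, brute-force
oracle in tests) from each epithelial cell to the nearest CD8+TIM3- T
cell, per spot; cases without targets are flagged undefined rather than
capped, and excluded from the cohort regression of log10(T-cell % of all
cells) on log10(median distance), which requires ≥3 eligible cases.

## Synthetic cohort

The generator emulates a TMA of tumor-rich carcinoma cores with planted,
exactly known geometry.  Each spot is a disk of radius 600 μm containing
5–7 epithelial deposit disks (radius 140–260 μm) packed without overlap,
separated by at least 40 μm of stroma — deposits with thin intersecting
stromal septa.  Greedy random packing is rerun 30 times per spot and the
tightest layout kept, giving ~50 % epithelial coverage consistently.
Because deposits are disjoint, the interface band — points within 15 μm of
a deposit circle, either side, hence ~30 μm wide, matching the analysis
radius scale — coincides exactly with distance to the epithelial boundary,
and ground-truth labels are closed-form.

Epithelial cells are a homogeneous Poisson process at 2500/mm² on the
deposits (sampled by thinning a spot-wide process, so counts are exactly
Poisson with mean density × deposit area); stromal cells at 1500/mm²
outside the deposits — realistic packed-tissue densities.  Cells keep
their *phenotype* from the generating process but their *truth label* from
geometry: epithelial or stromal cells falling inside the band are truth
"interface", since the real interface contains both.  Immune cells are
drawn as Poisson counts per spot (baseline CD8+TIM3- 150, CD8+TIM3+ 40,
macrophage 80 — T cells as roughly 2–6 % of cells with the exhausted
subset the minority), each cell's compartment drawn from per-type mixing
proportions π = (epithelial, interface, stromal):

* CD8+TIM3-: (0.10, 0.45, 0.45) — stroma- and interface-seeking;
* CD8+TIM3+: (0.35, 0.55, 0.10) — interface- and epithelium-enriched;
* macrophage: (0.20, 0.50, 0.30).

Placement is by rejection sampling from the spot (capped; a
measure-zero compartment with requested cells raises a generation error
naming the compartment).  Artifacts are scattered uniformly at 3 % of the
cell count.  The default ten-case scenario scales both T-cell subsets by
factors log-spaced from 0.08 to 1 — a planned ~12-fold span so the
realized, Poisson-noisy abundance span stays at or above one order of
magnitude across the cohort.  All randomness flows from one generator
seeded by (seed, case index), so cohorts are reproducible byte-for-byte.

What the generator does *not* emulate: irregular (non-disk) deposit
shapes, luminal macrophage niches, spatial clustering of immune cells
beyond compartment preference, intensity-based phenotyping noise, or
segmentation errors.  Passing recovery tests therefore show the pipeline
recovers compartment structure of this planted kind; they do not certify
performance on real morphology, where the interface is wigglier and
phenotyping imperfect.

## Numerical and design notes

* Problem sizes: the default cohort is 10 spots × ~2500 cells; recovery
  statistics in tests and the acceptance script aggregate 10 cohorts
  (100 spots), which gives stable proportions while a full run stays
  around a minute.
* Compartment recovery is scored with the adjusted Rand index between the
  k=3 assignment and geometric truth, pooled over the cohort.  Typical
  values are ~0.66: the pure compartments are recovered almost perfectly;
  the 30 μm band is thin, and immune-rich neighborhoods deep in a
  compartment can masquerade as interface (an intrinsic property of
  immune-weighted composition clustering, not a bug).
* k-means behind the region model is scikit-learn's; nearest-neighbor
  queries are scipy's cKDTree; the log–log fit is scipy's `linregress`.
  The tests check each against independent brute-force or closed-form
  oracles.
* Degenerate inputs: empty regions get area 0 and undefined (NaN)
  densities; coincident cells degenerate the area raster to at least one
  pixel; a case with no target T cells is excluded from the regression
  rather than imputed.
* Every case id is treated uniformly; excluding control/fiducial spots is
  left to the caller.
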