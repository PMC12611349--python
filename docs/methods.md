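# Methods

This note records the models and procedures implemented in `ipcz`, the
assumptions behind them, the parameter defaults and why they were chosen,
and the limits of what the synthetic experiments can show.

## Study lattice

The analysis grid is a 1° × 1° lattice over 18°S–25°N, 90°E–165°E: 43 rows
× 75 columns = 3225 cells. Cells are half-open intervals [x, x+1°) with the
outermost row/column closed, so the lattice partitions the box exactly and
boundary points are unambiguous. All areas use the planar approximation
1° ≈ 111 km (one full cell ≈ 12,321 km²); no equal-area projection is
applied, and longitudes never wrap (the box is far from the antimeridian).
Percentages "of the region" are fractions of all 3225 cells; land is not
masked.

## Diversity metrics

For each biological layer (ALL = non-threatened mollusks, TSP = threatened
mollusks, CSM = biogenic-habitat points) and each cell:

* **SE** — sampling effort, the raw record count;
* **SR** — distinct species (for CSM: distinct habitat types, 1–3);
* **SN** — Shannon-Wiener index −Σᵢ pᵢ ln pᵢ with pᵢ the share of the
  cell's records in species i. Natural logarithm (nats), the ecological
  default; per-species record counts stand in for abundance because the
  inputs are presence records.

SN = 0 whenever SR ≤ 1 and SN ≤ ln SR otherwise; these are enforced as
tested invariants along with scale-invariance of SN under uniform count
multiplication.

A species is **threatened** when its IUCN Red List category falls in a
configured set or it appears in CITES Appendix I/II. The default category
set is *all* listed categories (CR/EN/VU/NT/LC/DD): regional mollusk
conservation lists routinely include LC and DD species, and the union rule
is what makes a CITES-listed but IUCN-Not-Evaluated species threatened.
Species absent from the lookup are non-threatened. Cross-tabulations count
a dual-listed species (IUCN + CITES) once in per-class totals; the packaged
reference list (`ipcz.reference`) reconstructs a published regional
cross-tabulation at species level — 148 Gastropoda, 14 Bivalvia, 73
Cephalopoda (with two dual-listed species), 1 Polyplacophora, 173 Least
Concern in total, 12 species in Appendix II — and serves as a fixed
arithmetic check.

**Cleaning contract.** Occurrence rows are dropped (and counted per
reason) when coordinates are unparseable or out of range, dates are missing
or outside the 2000–2024 window, or the point falls outside the study box.
Duplicates on (species, lat, lon, date) are collapsed, coordinates compared
after rounding to 4 decimals (≈11 m) — finer than any grid decision the
pipeline makes. Cleaning is idempotent and order-invariant and never
mutates its input.

**Correlations.** The 9×9 Pearson matrix (3 layers × 3 metrics) is
computed, by default, over the union support: for each pair, cells where at
least one of the two layers has records. Including the ~84% of cells that
are empty in both layers would manufacture agreement from shared zeros.
The all-cells variant remains available behind a flag since the choice is
genuinely open.

## Composite indices and hotspot detection

Per metric, the three layers are min-max normalized ((x−min)/(max−min); a
constant layer maps to zeros) and combined as

    composite = 0.35·ALL + 0.45·TSP + 0.20·CSM,

the expert weighting that favors the sparse but high-conservation-value
threatened layer, then the broad community layer, then habitat as an
enabling condition. Normalization precedes weighting, matching the stated
order of operations in this analysis tradition. Weights must sum to 1
(tolerance 1e-9, fatal otherwise).

**Getis-Ord Gi\*.** For cell i with binary weights w_ij = 1 over its
contiguity set plus itself (queen by default; rook and row-standardized
variants available):

    z_i = [Σ_j w_ij x_j − X̄ W_i] / [S · √((n Σ_j w_ij² − W_i²)/(n−1))]

with W_i = Σ_j w_ij and X̄, S the mean and *population* standard deviation
over the n analysis cells. The implementation is a 3×3 convolution over the
lattice; a naive double-loop evaluation of the same definition serves as an
independent oracle in the tests (agreement to 1e-10 on random 20×20
fields).

**Analysis background.** `gi_star` supports two supports:

* `background="all"` — every lattice cell enters n, X̄, S (the literal
  formula; the oracle tests use this);
* `background="occupied"` — only cells with a positive composite form the
  analysis set: the neighbor graph, n, X̄ and S cover those cells alone,
  and empty cells are reported not-significant.

The pipeline default is `occupied`. With an 84%-empty ocean in the
background, the global variance collapses and *every* occupied neighborhood
becomes "extreme": on realistic clustered fields the all-cells variant
flags 10–14% of the region at 99% confidence, which is not a usable
hotspot screen. Restricting the statistic to cells with data — exactly
what happens in the standard GIS workflow where only cells with values
become polygons — restores the expected regime (≈1–3% of the region per
metric, maximal Z-scores in the 6–12 range) while leaving hotspot extents
expressed as fractions of all 3225 cells.

Z-scores are binned at the two-tailed normal quantiles: |z| ≥ 1.645 (90%),
≥ 1.960 (95%), ≥ 2.576 (99%), hot for positive z and cold for negative.
No multiple-testing correction is applied by default (an FDR option
exists but is off): the tier thresholds are treated as the method's
convention, not as calibrated per-cell error rates.

**Priority areas.** The priority mask is the union of the three metrics'
hot99 cells, with per-cell provenance (which metrics contributed).
Contiguous sites are 8-connected components, numbered in decreasing size.
Only hotspots are interpreted; cold tiers are computed and stored but play
no further role.

## Environmental attribution

Eleven per-cell environmental variables (T °C, Bm m, WV m/s, Sal psu, Si
mol/m³, Po mmol/m³, PP mmol/m³, pH, DO mmol/m³, No mmol/m³, Ir mmol/m³)
are cell-averaged from point values where needed. The regression model is
gradient-boosted trees (xgboost) with fixed, seeded hyperparameters
(300 trees, depth 3, learning rate 0.1, no subsampling, single thread) —
deterministic by construction; hyperparameter search is an explicit
opt-in, off by default, because a moving model would make the attributions
irreproducible. The attribution layer only requires `predict`, so any
regressor can be plugged in.

**Exact Shapley values.** For observation i and feature j,

    φ_ij = Σ_{S ⊆ F\{j}} |S|!(p−|S|−1)!/p! · [v_i(S∪{j}) − v_i(S)],

with the interventional value function v_i(S) = mean prediction over
background rows whose features in S are replaced by observation i's
values. All 2^p coalitions are enumerated (p = 11 → 2048), which keeps the
attribution exactly faithful to the axioms: efficiency
(Σ_j φ_ij = prediction − baseline) holds to machine precision and is
asserted at 1e-8, dummy features get exactly zero, and symmetric features
get equal shares. The cost is 2^p × |background| model evaluations per
observation, so the pipeline attributes a seeded subsample (default 60
observations against a 30-row background) rather than every cell; these
sizes are the package's default problem size and are configurable.

A permutation-sampled estimator handles p > 15 and converges to the exact
values; when all p! orderings fit within the permutation budget it cycles
whole passes through them (balanced sampling) so residual Monte-Carlo noise
comes only from the remainder.

Importance is the per-feature mean |φ|; the **direction** of a feature is
the sign of the Pearson correlation between φ_ij and x_ij (negative =
higher values push predictions down). Significance marks, when requested,
come from a seeded permutation test on mean |φ| (199 refits under permuted
response); this is expensive and intended for small fits.

## Conservation-gap analysis

Fishing records are classified by gear through an editable total mapping
(unknown gears → ambiguous). Shares are computed over classified effort
only. Closed-season statistics compare the May–July window with the year:
the mollusk share inside the window, the annual mollusk share, and the
fraction of each class's annual hours that falls inside the window.

Effort hotspots are cells at or above the 0.80 quantile of annual
class-total hours, the quantile taken over cells with positive effort
(counting the empty ocean would make the threshold trivially small; a flag
restores the all-cells variant). Ties at the threshold are included. The
ln(1+x) map used for visualization is monotone and provably never changes
the hotspot set — asserted in the tests.

MPA coverage of the priority mask is reported two ways: the area-weighted
mean fraction of each priority cell's box intersected by the MPA union
(planar geometry; cells are equal-size squares under the 111 km/degree
approximation), and the binary fraction of priority cells touched at all.
Published coverage figures of this kind rarely say which rule they use, so
both are first-class outputs. Invalid polygons are fatal with the feature
index; the focal year defaults to the latest year with all 12 months of
data. The final overlap report intersects priority cells, MPA-covered
cells and effort hotspots — the "protected on paper yet under high
pressure" set.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical features the analysis actually
relies on, at ≈1/8 of the real data volume:

* **Occurrences** (default 6000 records, 300 species): a marked Thomas
  cluster process with 60 cluster centers uniform in the box. Cluster
  sizes follow a Zipf(2.0) series — the top survey region holds ≈10% of
  all records, matching the observed dominance of a single 1° cell in
  regional extracts. Clusters are anisotropic filaments (σ_major =
  8 × 0.3°, σ_minor = 0.3°/8, random orientation): survey records string
  along coasts and reef tracts rather than filling circular blobs, and
  this 1-D geometry is what keeps 3×3 neighborhood sums — and hence Gi*
  false positives — realistic. Each cluster draws species from its own
  120-species window of the pool (species turnover between regions) with
  geometric rank-abundance (decay 0.93) within the window; 5% of records
  scatter uniformly. Occupancy lands at ≈17% of cells, the sparse regime
  reported for the real region (≈16%).
* **Threatened subset**: 15% of species carry a status entry, IUCN
  categories skewed toward LC/DD, ≈10% with CITES Appendix II, and a few
  CITES-only (IUCN NE) species so the union rule is exercised.
* **Habitats** (≈2750 points; coral 1400 > mangrove 1100 > seagrass 250,
  mirroring the observed coverage ordering): drawn from the *same* cluster
  frame as the occurrences, each habitat using a random 60% subset of the
  regions. Co-location is what produces the positive CSM-vs-mollusk
  correlations (r ≈ +0.35–0.40) seen in real data.
* **Planted hotspots**: the default scenario plants three well-separated
  cells; each receives 5 × (n_records/n_clusters) extra records placed
  uniformly inside the cell with species drawn uniformly from the whole
  pool — simultaneously extreme in effort, richness and evenness. Planted
  recovery across seeds is the pipeline's end-to-end detection check
  (mean recovery 100%, non-planted cells in the mask ≈1.6% of the grid).
* **MPAs**: rectangles centered near cluster regions with jitter
  (protected areas concentrate along the same coasts), giving priority-mask
  coverage in the ~20–40% range rather than degenerate zero overlap.
* **Effort**: per cell-month-gear log-normal hours (μ=3, σ=1.2 log-hours),
  three years, mollusk-targeting gears at twice the base scale (annual
  mollusk share ≈ 64%, like the >60% shares reported for this fishery) and
  halved during May–July to emulate the closed season.
* **Environment**: each of the 11 variables is an independent Gaussian
  random field (white noise smoothed with σ = 3 cells) at plausible
  tropical-ocean scales. The linked response used in attribution tests is
  y = 1.0·PPz − 0.6·Tz + 0.4·Bmz + 0.3·PPz·Bmz + ε (z-scored predictors,
  ε ~ N(0, 0.1)), min-max scaled — a known ground truth with a dominant
  positive productivity effect, a negative temperature effect, and an
  interaction the exact attribution must split correctly.

Not emulated: real coastline geometry or land masking, species names and
taxonomy services, temporal trends within 2000–2024, spatial correlation
*between* environmental variables, and any dependence of occurrence
density on the environmental fields (the attribution tests use the
synthetic link precisely so the truth is known). Consequently, passing
tests show that the *methods* behave correctly on data with the right
statistical structure — not that the package's outputs on the real region
would numerically match any published map.

## Numerical choices and degenerate inputs

* Min-max normalization of a constant layer yields zeros (not NaN).
* A zero-variance Gi* field yields z = 0 everywhere, all not-significant.
* Pearson r with a zero-variance vector is reported missing (NaN), never 0.
* Shapley efficiency tolerance 1e-8 in exact mode (observed error is
  machine epsilon); sampled mode is seeded.
* Duplicate keys compare coordinates at 4 decimals; dedup keeps one
  representative chosen by a stable sort, so the kept set is independent of
  input order.
* All generator streams are split per product (occurrences, status,
  habitats, MPAs, effort, environment), so generating one table never
  perturbs another; identical scenarios are byte-identical.
* Seeds are plain integers; every stochastic step takes one.

## Known limitations

* The occupied-background Gi* (the default) conditions on where data
  exists; it detects clustering of *high values among sampled cells* and
  cannot speak to unsurveyed ocean. This mirrors the survey-effort caveat
  inherent to occurrence-based hotspot mapping.
* Record counts proxy abundance; SE and SN inherit survey-effort bias by
  construction (SE is, in fact, the effort layer).
* Exact Shapley cost grows as 2^p; beyond 15 features only the sampled
  estimator is practical.
* The permutation significance test refits the model per permutation and
  is quadratic-feeling in practice; defaults keep it off.
* Gap statistics depend on the gear→class mapping, which real datasets do
  not standardize; the mapping ships as data, not code.
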