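# ipcz — spatial prioritization of marine mollusk biodiversity

`ipcz` is an analysis pipeline for identifying priority conservation areas
for marine mollusks in the Indo-Pacific Convergence Zone (IPCZ), the
tropical study box 18°S–25°N, 90°E–165°E. It is written for spatial
ecologists and conservation planners who want the full chain — from raw
occurrence tables to a conservation-gap report — as tested, reusable,
fully seeded code.

The pipeline:

1. **Gridding** — a 1° lattice over the study box (43 × 75 = 3225 cells,
   each ≈ 12,321 km² at 111 km/degree).
2. **Diversity layers** — per cell and per biological layer (ALL =
   non-threatened mollusks, TSP = threatened mollusks, CSM =
   coral/seagrass/mangrove habitat points): sampling effort SE (record
   count), species richness SR, and the Shannon-Wiener index
   SN = −Σᵢ pᵢ ln pᵢ, plus the 9×9 cross-layer Pearson correlation matrix.
3. **Hotspots** — each metric's three layers are min-max normalized and
   combined with expert weights (0.35·ALL + 0.45·TSP + 0.20·CSM); the
   composite is screened with a from-scratch **Getis-Ord Gi\*** statistic

   z_i = [Σ_j w_ij x_j − X̄ W_i] / [S √((n Σ_j w_ij² − W_i²)/(n−1))]

   with binary queen-contiguity weights (w_ii = 1), tiered at the
   two-tailed normal quantiles 1.645/1.960/2.576 (90/95/99% confidence).
   The union of the three metrics' 99% hotspot cells is the **priority
   conservation area**, labeled into contiguous sites.
4. **Environmental attribution** — a seeded boosted-regression model of the
   composite index on 11 per-cell environmental variables (temperature,
   bathymetry, velocity, salinity, silicate, phosphate, primary
   productivity, pH, oxygen, nitrate, iron), decomposed with **exactly
   computed Shapley values** (brute-force enumeration of all 2¹¹ = 2048
   feature coalitions), ranked by mean |φ| with signed directions.
5. **Gap analysis** — gear-classified fishing effort (mollusk /
   non-mollusk / ambiguous), May–July closed-season statistics, top-20%
   effort hotspot cells, MPA coverage of the priority mask, and the
   "protected yet still under pressure" overlap set.

Because the real inputs (aggregator occurrence extracts, habitat layers,
protected-area polygons, vessel-effort grids) cannot be bundled, the
package ships a first-class synthetic generator (`ipcz.synthetic`) that
reproduces the statistical structure the analysis assumes: Zipf-sized
anisotropic survey clusters, species turnover between regions, a threatened
subset, co-located habitat filaments, seasonal gear-stratified effort, and
environmental surfaces with a known link for attribution-recovery tests.

## Worked example

Run the numbered drivers from the repository root (all seeded; default 42):

```bash
python analysis/01_simulate.py          # synthetic inputs -> results/data/
python analysis/02_clean_and_tabulate.py
python analysis/03_diversity.py
python analysis/04_hotspots.py
python analysis/05_attribution.py
python analysis/06_gap_analysis.py
```

Selected output from a run with the default seed:

```
ALL: occupancy 15.97%; max SE 520 (cell 2941); max SR 215; max SN 5.23 nats
  r(CSM_SE, ALL_SR) = +0.36  (p = 5.9e-19)

SE: hot tiers {'hot90': 5, 'hot95': 4, 'hot99': 33} (1.30% of the region), Z_max 11.77
SR: hot tiers {'hot90': 8, 'hot95': 23, 'hot99': 58} (2.76% of the region), Z_max 8.54
SN: hot tiers {'hot90': 5, 'hot95': 11, 'hot99': 23} (1.21% of the region), Z_max 4.42
priority mask: 63 cells in 7 sites (1.95% of the region)

importance ranking (mean |phi|, direction):
     mean_abs  direction  rank
PP     0.0346          1     1
T      0.0241         -1     2
Bm     0.0111          1     3

closed season (May-Jul): mollusk share in window 49.42% vs annual 63.76%;
window holds 13.93% of annual mollusk effort (non-mollusk: 25.09%)
MPA coverage of the priority mask: 19.57% area-weighted
```

Reading this: about 16% of the grid cells hold any mollusk record (the
sparse-occupancy regime typical of this region); each composite index
yields roughly 1–3% of the region as hotspots; their 99% union gives a
small set of priority sites. The attribution recovers the generator's
ground truth — primary productivity is the dominant positive driver,
temperature the negative one, bathymetry third — and the gap analysis shows
a fishery whose mollusk-directed share drops during the May–July closed
season, with only ~20% of the priority area covered by protected areas.

The same stages are scriptable through one config:

```bash
ipcz run --config my_run.yaml --out runs/demo   # writes MANIFEST.json
```

## Layout

```
src/ipcz/        library: grid, synthetic, ingest, reference, diversity,
                 hotspots, attribution, gap, pipeline, cli
analysis/        numbered narrative drivers (01_simulate ... 06_gap_analysis)
tests/           pytest suite (unit, property and end-to-end checks)
scripts/         acceptance.py
docs/methods.md  models, assumptions, parameter choices, limitations
```
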