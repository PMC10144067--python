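# Methods

## Problem setting

A breeding trial sows many germplasm accessions in randomized replicate
plots across one field. If the field were homogeneous, replicate plots of
one accession would carry exchangeable plant heights and any height
difference between plots would reflect genetics. On sloped ground that
assumption fails: drainage follows the slope, the low corner stays wet, and
growth there is suppressed regardless of genotype. `fieldlisa` quantifies
this spatial dependence at plant resolution, delineates the affected area,
and expresses it as management zones for blocking.

The carrier of growth status is plant height, derived from two co-registered
elevation rasters in a local planar CRS (meters): a digital terrain model
(DTM, bare ground) and a digital surface model (DSM, top of canopy).

## Canopy height model and per-plant extraction

Height is DSM − DTM per cell; nodata in either input propagates, and
negative differences (reconstruction artifacts) can be clamped to zero.
(The working description of this step in parts of the agronomic literature
is sometimes phrased the other way around, "surface subtracted from
terrain", which would be uniformly negative; the subtraction implemented
here is the one that yields canopy heights.)

Per plant, the height estimate is the **maximum** height-map value over all
cells whose *centers* lie within 0.20 m of the sowing point (a 0.40 m
diameter buffer). The maximum is deliberate: the buffer must catch the apex
of a thin, tall plant whose highest point may sit a few cells off the sowing
coordinate. The cell-center membership rule avoids partial-cell ambiguity.
Consequences worth knowing:

- enlarging the buffer can only increase estimates (monotonicity), and
- when buffers of adjacent plants overlap a taller neighbor can leak into a
  shorter plant's buffer. At the default 25 cm plant spacing and 0.10 m
  crown radius the apex of a neighbor is outside the buffer's reach of its
  own crown, so the noise-free pipeline recovers true heights exactly.

Heights are standardized jointly over all plants of one acquisition date:
z = (h − mean)/SD with the **population** (divide-by-N) SD. This matches the
scaling of the local statistic below (m = ΣZ²/N becomes exactly 1), and
makes standardization idempotent. Constant heights raise a degenerate-
variance error rather than producing NaNs.

Plants with z below −1.646 (≈ the lowest 5% of a standard normal) are
flagged as outliers — failed extractions, non-germinated positions — and
excluded from all spatial stages. z-scores are **not** recomputed after
removal. The cutoff is kept at the protocol value −1.646 even though the
5% normal quantile to three decimals is −1.645; the removal behavior is what
matters and the difference is ~0.0002 in removed fraction.

Extraction quality is validated per plot: OLS of true (field-measured) on
estimated plot-maximum height; slope (regression coefficient, RC) and R²
are reported. On the default synthetic field R² ≈ 0.999.

## Local Moran's I with conditional permutation

For location *i* with standardized value Z_i,

    I_i = (Z_i / m) · Σ_j W_ij Z_j ,   m = Σ_i Z_i² / N .

Weights are a **binary distance band**: W_ij = 1 iff 0 < d_ij ≤ 1.75 m,
symmetric, no self-neighbors. The 1.75 m default is the farthest distance at
which every plant still reaches a neighbor in an adjacent plot under the
default layout (25 cm in-plot spacing, 50 cm plot gaps). Inverse-distance
weights (1/d inside the band) are available as an option
(`style="inverse_distance"`); binary is the default because the 0/1
neighbor definition is the one the plot-level analysis is built on.
Isolated points (no neighbor in the band) are flagged, reported NS, and
never silently dropped; if *every* point is isolated the weights builder
raises.

Useful identities, both enforced by tests against brute-force oracles:
Σ_i I_i = S0 · I_global (S0 = ΣΣW_ij), and the OLS slope of the
row-standardized spatial lag on z equals global Moran's I (the Moran
scatterplot property).

**Inference** is by conditional permutation. For each i, Z_i stays in
place; its |N(i)| neighbor slots are refilled M = 999 times with values
drawn *without replacement* from the other N − 1 observations, independently
across points, all from one seeded generator stream. The pseudo p-value is
(R + 1)/(M + 1), so its floor is 1/(M + 1) = 0.001 at the default M.

*Sidedness.* The default test is the fixed upper tail: R counts permuted
I_i ≥ observed. Under an exchangeable null this pseudo p-value is uniform,
so the flagged fraction at any α equals α — the property the calibration
suite checks (measured 0.0096 at α = 0.01 over 50 replicates of 200 random
points). The upper tail is also exactly the direction that matters for
cluster regions: both H-H and L-L membership means *positive* local
autocorrelation. The alternative `"directed"` rule (one-sided toward the
observed side of the permutation mean) additionally picks up significant
spatial outliers (L-H, H-L), but necessarily flags ~2α under the null
(each tail contributes α; measured 0.019 at α = 0.01) — callers who use it
for calibrated inference should halve α.

*Ties.* Permuted statistics equal to the observed one count as "as
extreme". A relative epsilon (1e−12) absorbs summation-order round-off when
a permutation happens to redraw the observed neighbor set — visible at
small N, negligible at field sizes.

*Quadrants.* Sign classification of (Z_i, lag_i): (+,+) H-H, (−,−) L-L,
(−,+) L-H, (+,−) H-L, with zeros assigned to the "high" side (≥ 0 → H).
Labels depend only on signs, so any positive rescaling of a weight row
(e.g. row standardization) cannot change membership. Significance labels:
class = quadrant if pseudo p ≤ α (inclusive at α), else NS; default
α = 0.01.

*Determinism.* I_i, lags and quadrants are order-invariant deterministic
functions of the inputs. Pseudo p-values are deterministic under a fixed
seed; reordering points permutes the RNG stream, so p-values are
reproducible per ordering (the statistics themselves never change).

The permutation sampler draws index rows by rejection (duplicate rows are
redrawn) when the neighbor count k is small relative to the pool, and by
arg-partitioning uniform keys when k² exceeds the pool — O(M·k) typical
cost per point instead of O(M·N).

## Cluster regions and zones

Per-plant classes aggregate to plots: a plot joins the low-growth region
when ≥ `min_fraction` (default 0.5) of its non-outlier plants are L-L;
high-growth analogously with H-H. The 0.5 default is this package's own
operationalization of "intensively clustered" — hand-drawn region polygons
are not reproducible; a majority rule at plot resolution is. At
min_fraction ≤ 0.5 a plot could qualify for both regions: the larger
fraction wins and an exact tie raises a consistency error. Raising
min_fraction never grows a region. Regions are unions of plot rectangles
(no smoothing, no interpolation). Cross-date similarity is the Jaccard
index of the two plot-id sets (undefined → None with a warning when both
are empty).

Zones: A = low-growth plots, B = high-growth, C = the rest (bare plots are
always C). The partition is total and disjoint by construction.

## Replicate similarity tests

Per germplasm, the plant heights of its replicate plots are compared with
the tie-corrected Kruskal–Wallis test (chi-square reference with
groups − 1 df; at ~15 plants per plot the approximation's type-I error is
0.0975 at α = 0.1 and 0.0081 at α = 0.01 over 50k simulations). Pairwise
follow-up is Dunn's z on pooled tie-corrected ranks with Benjamini–Hochberg
step-up applied within each germplasm's comparison family (matching how the
results are tabulated, one family per accession). Star coding of p-values:
`**` below 0.01, `*` below 0.1, blank otherwise.

Two-group comparisons (e.g. soil moisture of low- vs high-altitude ground)
use the Wilcoxon rank-sum test with an explicit `alternative`; the p-value
is exact (full enumeration) for min(n_a, n_b) ≤ 8 without ties, normal
approximation without continuity correction otherwise. The direction of the
hypothesis is always the caller's choice — the operation takes no stance on
which region "should" be wetter.

## Synthetic field generator

What it emulates, and the defaults that define the standard conditions:

| parameter | default | rationale |
|---|---|---|
| design | 24 germplasms × 3 reps, 15 plants/plot | the trial design the pipeline targets |
| plant / plot spacing | 0.25 m / 0.50 m | sowing protocol |
| plot rectangle | planted row + 0.25 m margin | spacings are specified, plot dimensions are not; derived |
| germplasm means | Uniform(1.5, 3.0) m, seeded | kenaf-like stature late in the season; 2× genetic spread keeps the genetics-vs-environment attribution non-trivial |
| terrain | plane dropping 2 m toward azimuth 315° + smoothed noise (SD 0.03 m) | high-southeast / low-northwest field |
| suppression | logistic ramp of elevation between the field's 10th–40th percentiles, floor 0.6 | waterlogging hits the low corner, saturates on high ground; monotone in elevation |
| height noise | SD 0.05 m | plant-to-plant variability |
| crown | cosine-tapered disc, radius 0.10 m, exact apex | any profile with an exact apex satisfies the recovery contract |
| render noise | SD 0.02 m | surface-reconstruction error |
| cell size | 0.05 m | 1.4 cm/px imagery is available by config but wasteful for a synthetic surface |

Plants sit on a single row per plot (ridge planting); non-germinated
accessions are modeled as `bare_germplasms` whose plots stay bare ground
(none by default — non-germination is an accident of a particular trial,
reproduced in tests, not a design condition).

Every generator is a pure function of parameters and an explicit integer
seed. With all noise terms zero the full pipeline returns true heights
exactly; with the environmental effect off, heights are exchangeable across
the field, giving the null configuration for LISA calibration.

What it does **not** emulate: photogrammetric reconstruction (occlusion,
matching failures, dome artifacts), georeferencing error, lodging, canopy
closure between neighboring plants late in the season, weather damage, or
within-plot competition. Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under controlled
conditions — not that a particular real field will yield R² = 0.99; real
UAV extractions are substantially noisier.

## Problem sizes used by the test and acceptance suites

Chosen as the package's standard verification workloads: outlier-rule
calibration on 10⁶ normal draws; LISA null calibration on 200 points ×
999 permutations × 50 replicates; height recovery and region recovery on
the default 72-plot field (two dates × three seeded replicates for
persistence); rank-test calibration on 2,000–5,000 simulations at 15
plants/group; exhaustive permutation enumeration at N ≤ 7; brute-force
global-Moran equivalence on 50 random 25-point instances.

## Known limitations

- The pseudo p-value floor 1/(M+1) makes multiple-testing behavior at
  field scale coarse; no FDR control is applied across plants (by design —
  the protocol thresholds raw pseudo p-values).
- Buffer-max extraction biases per-plant heights upward in dense canopies;
  plot-maximum validation is robust to this, per-plant values less so.
- Region delineation is plot-resolution; sub-plot gradients are invisible.
- Conditional permutation treats plants as exchangeable units; it does not
  model the two-level structure (plants within plots) and will attribute
  strong within-plot similarity of a clustered short germplasm to space.
  The replicate-similarity tests exist precisely to separate the two
  readings.
- Rasters are plain Esri ASCII grids with a local planar CRS; no geodetic
  metadata is carried.
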