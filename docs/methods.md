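# Methods

## The screening model

The package screens species for future heat exposure by comparing a
baseline *heat envelope* with projected conditions under a scenario
ensemble. All quantities derive from a single bioclimatic variable,
BIO5 — the maximum temperature of the warmest month (°C) from a
multi-decadal climatology — sampled over species range polygons on one
consistent grid.

For each species two baseline envelopes are computed: over the
historical range and over the (typically contracted, nested) current
range. An envelope is strictly the observed `[min, max]` of cell values
— no quantile trimming or density thresholds — so the thermal maximum
(TM) is an attained value of the baseline field. Kernel-density exports
exist for exposure plots but play no role in classification.

Each of the *k* future layers is sampled over the **current** range and
scored against both baseline envelopes: the overlap is the percentage of
cells (optionally area-weighted) whose projected BIO5 does not exceed
the envelope's TM. The ensemble mean and standard error
(`SE = SD(k−1 denominator)/√k`) feed the three-tier rules at a 50 %
threshold, applied to the conservative lower bounds `mean − SE`: low
risk requires both overlaps above the threshold, moderate risk only the
historical one, high risk neither. The `upgraded` flag records when the
SE adjustment changed the tier relative to the raw means.

Assumptions worth stating explicitly:

* **Heat, not cold.** The default overlap is one-sided (upper tail): a
  cell projected *below* the envelope minimum still counts as within,
  because the construct is exposure to novel heat. A `two_sided` mode is
  available for sensitivity analysis.
* **Strict criteria.** The rules use strict `>`: an overlap of exactly
  50 % fails the criterion (conservative). Exceedance of a TM is
  likewise strict — equality counts as within, since the TM is itself an
  attained envelope value.
* **One-directional upgrade.** Only `mean − SE` is tested; a mean below
  threshold is never rescued by `mean + SE`.
* **Nested epochs.** When the current polygon is nested in the
  historical one, `TM_curr ≤ TM_hist`, so historical overlap bounds
  current overlap per scenario — a property the tests assert.

Refugia maps use the historical TM as the benchmark: each
historical-range cell is classified by the number of scenarios that keep
it at or below the benchmark — *all* (refugium under every future),
*some*, or *none* — and area fractions over the range sum to one. A
switch to benchmark against the current TM exists for exploration but is
off by default.

Translocation sites are treated as point locations sampled at the
containing grid cell (no interpolation). "Mildest" and "most extreme"
scenarios are defined **per site** as the minimum and maximum projected
value at that point across the ensemble, and the "mean scenario" is the
arithmetic mean of the k values; a globally fixed mildest GCM×SSP pair
would understate per-site spread where warming patterns differ
spatially.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| overlap threshold | 50 | % | the published tier boundary; configurable in (0, 100) |
| overlap mode | `upper` | — | heat exposure is an upper-tail construct |
| inclusion rule | `center` | — | cell-center-in-polygon, the common zonal convention and unbiased; `all_touched` (with a warning) for ranges that miss every center |
| area weighting | off | — | min/max are weight-invariant; cos(latitude) weights affect only overlap proportions on geographic grids |
| ensemble size k | 15 | scenarios | 5 GCMs × 3 SSPs |
| SE convention | SD(k−1)/√k | % | the SEM of the ensemble-mean overlap |
| Dunn adjustment | `none` | — | raw pairwise p-values by default; `holm`/`bonferroni` available |

Grid alignment is enforced, never repaired: layers must share shape,
transform and CRS, and the nodata mask is unified to the union across
layers so every per-scenario denominator is identical. Silent
resampling would perturb envelope extrema, which are order statistics
and maximally sensitive to interpolation.

## Statistical tests

Categorical trait–tier associations use Pearson's chi-squared test of
independence without continuity correction (asymptotic p); tables with a
zero expected count raise an error rather than returning a meaningless
statistic. Continuous traits (log10 body mass, log10 range areas, Δ,
envelope widths, % arid, % remnant — logs applied at load) use the
tie-corrected Kruskal–Wallis H with pairwise Dunn post hoc z tests:

    z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)]

with `ΣT = Σ(t³ − t)` over tie groups. All-identical samples return
H = 0, p = 1 (no evidence) instead of erroring. Report percentages are
rounded half-away-from-zero to whole percent to match conventional
printed tables.

## What the synthetic generator emulates — and what it does not

The generator produces a baseline grid with a linear latitudinal
temperature gradient (default 400 × 160 cells at 0.05°, 1 °C/° lat,
i.e. a 20 °C span with 0.05 °C row steps), and k future grids as
baseline + additive warming fields (uniform, west–east gradient, or
smooth "patchy") whose spatial means span a configurable range, default
+1 to +4 °C — a realistic mid-century envelope of hottest-month warming
across low- to high-emission pathways. Ranges are unions of whole cell
rectangles, so the cell-center inclusion rule is exact and every
envelope and overlap is known at construction time.

Species construction works backwards from the targets: because the
ensemble-mean overlap equals the cell-average of per-cell scenario
survival fractions, the generator computes each candidate cell's
fraction from the actual future grids and allocates cells so the
fractions average to the requested overlaps (structural cells pin the
current and historical TM and the envelope minimum). Achieved overlaps
are checked against the targets to ±2 percentage points and the exact
per-scenario overlap lists are emitted as ground truth; specs that are
mathematically unrealisable raise an infeasibility error instead of
silently drifting. One such case is intrinsic, not an implementation
limit: a species whose current TM sits further below its historical TM
than the ensemble's maximum warming offset can never lose historical
overlap (every projected value stays under TM_hist), so e.g.
Δ = 9.5 °C with a target historical overlap of 80 % under ≤ +4 °C
warming is rejected, while Δ = 9.5 °C with ~100 % historical overlap is
constructed and recovers Δ to within one grid step. The default
moderate-tier spec therefore uses Δ = 2.5 °C with overlaps (30, 80).

What passing on synthetic data does *not* show about real data: the
generator has no spatially autocorrelated noise structure, no coastline
or terrain-driven nodata patterns, no disagreement between scenario
spatial patterns beyond the chosen field family, and polygon boundaries
never cut cells. Real-range extraction is therefore exercised by the
randomized polygon-versus-oracle tests, not by the constructed species.

## Numerical choices

* Grid I/O is the ESRI ASCII format with values written at 17
  significant digits, so write→read round-trips are bit-exact for
  float64; an optional `.crs` sidecar carries the CRS string.
* Ties at an envelope bound: `value ≤ TM` counts as within, everywhere
  and consistently (pipeline, generator truth, site screening).
* `SE = 0` when k = 1 (a single scenario carries no spread information).
* Cell extraction orders values row-major; envelopes are invariant to
  that order, which a property test asserts.
* Invalid polygons are repaired constructively (every positive-area lobe
  kept); a bow-tie retains the area of both triangles rather than losing
  the odd-winding half as buffer(0) would.
* Degenerate KDE inputs (single cell or zero variance) fall back to a
  single Gaussian bump (default bandwidth 0.5 °C) so density exports
  always integrate to 1.

## Problem sizes and determinism

The test suite and the acceptance script run the tier-recovery
experiment at 50 seeded species per tier (150 total) on one 400 × 160
grid with 15 scenarios, check refugia maps against an exhaustive
(cell × scenario) loop, and check extraction against a per-cell
point-in-polygon loop on 20 random convex polygons over a 50 × 50 grid —
sizes chosen to make the oracles exhaustive yet quick. All randomness
flows through explicit integer seeds (numpy `default_rng`); the full
pipeline is byte-deterministic at the CSV level for a fixed config and
seed.

## Known limitations

* Exposure screening only: no dispersal, microclimate buffering,
  physiology or demography — the framework triages species for deeper
  mechanistic modelling, it does not replace it.
* Envelopes are order statistics of the sampled cells, so results at
  very coarse grids or for tiny ranges are sensitive to the inclusion
  rule; `all_touched` trades that for a known widening bias.
* No reprojection/resampling: inputs must be prepared on one grid.
* Vector input is GeoJSON; grids are single-band ASCII rasters. Other
  formats should be converted upstream with standard GIS tooling.
* The chi-squared tests use the asymptotic distribution; with the small
  per-cell counts typical of 36-species tables, p-values are indicative
  rather than exact (no Monte-Carlo option is provided).
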