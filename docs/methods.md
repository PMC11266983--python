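# Methods

## The model

`phenoniche` predicts the intra-annual timing of an ecological event —
insect emergence, mushroom fruiting, flowering — from presence-only,
time-stamped occurrence records and daily gridded weather. The underlying
idea is the *relative phenological niche*: the set of temporal environmental
conditions (an n-dimensional hypervolume over weather histories) within
which the event occurs, defined relative to environmental drivers rather
than to the calendar. Each observation record samples one point of that
hypervolume: the weather history at its place and date.

To delimit the hypervolume with discriminative learners, the package
contrasts observations with **temporal pseudoabsences**: for each event
record, `n_per = 12` synthetic records with *identical coordinates* but
dates drawn uniformly at random from the study span. These sample the
conditions *available over time* at places where the event is known to
occur. A classifier separating the two classes therefore estimates
`P(conditions within the niche)`, a daily, spatially explicit probability
once applied to every grid cell.

The 12:1 ratio follows common practice for this family of models; it is
configurable, and both learners compensate for the imbalance (below).

## Workflow

1. **Quality filtering.** Records need a full date (day, month, year) and
   coordinates with uncertainty below 0.1°. Records dated the first of a
   month at exactly 00:00:00 are removed (a common database artefact of
   month-only precision). Photo/evidence flags are accepted as pre-supplied
   booleans. Rules apply in a fixed order (date completeness → year range →
   midnight-first-of-month → coordinate bounds → uncertainty → photo →
   evidence) so every rejection carries one deterministic reason.
   Metre-valued uncertainties convert to degrees at the record's latitude
   using the *larger* of the latitudinal and longitudinal spans — a record
   passes only if precise along both axes. Records with a missing
   uncertainty field are kept by default (the field is commonly absent);
   this is configurable.
2. **Spatial bias.** One record per (day, 0.25° cell), chosen uniformly;
   then counts per 250 km block (tiled in a Lambert cylindrical equal-area
   projection on the authalic sphere, so blocks have equal area at every
   latitude) are capped at the Q3 + 1.5·IQR upper-outlier threshold,
   quartiles taken over non-empty blocks with the linear-interpolation
   convention, fractional caps rounded half-up. With fewer than four
   non-empty blocks quartiles are meaningless and the step is a warning
   no-op.
3. **Temporal bias (optional).** A benchmark taxon whose record stream is
   assumed to track observer effort (not phenology) is contrasted with an
   equal-sized background of the same coordinates and uniform random dates,
   via a binomial GLM on day-of-week, month (references: Friday, April) and
   same-day mean temperature, precipitation and wind. Event records are then
   resampled with inclusion probability inversely proportional to predicted
   effort. The textbook normalisation `p_i = min(s)/s_i` makes retention
   hostage to the single least-observed record: with realistic effort spread
   the corrected dataset can collapse to a few percent of its input, and any
   skill difference then measures sample size, not bias. The pipeline
   therefore truncates the weights at the 10th-percentile score
   (`stabilize = 0.10`, `p_i = min(1, q10/s_i)`), the standard remedy for
   extreme inverse-probability weights; `ipw_resample` retains the exact
   min-normalisation as its default contract, plus a fixed-size weighted
   draw as an alternative.
4. **Features.** Trailing-window summaries of the six weather variables
   (tmin/tmean/tmax °C, precipitation mm/day, snow depth cm, wind m/s) at
   the record's grid cell, windows {1, 3, 7, 14, 30, 60, 90, 180, 365} days
   *including* the record's day (so the 1-day window is the same-day value),
   means everywhere except accumulated precipitation; plus raw coordinates.
   6 × 9 + 2 = 56 features by default; the set is fully configurable.
   Records without full lookback are dropped with a logged reason, never
   imputed. Before *every* training event a greedy filter removes columns
   until all pairwise |Pearson r| < 0.8: repeatedly find the worst pair and
   drop its member with the larger mean absolute correlation to everything
   else (ties to the later column) — so the kept set can differ between
   cross-validation folds, as it should.
5. **Learners.** Two members handle the 1:12 imbalance differently:
   - a **balanced random forest** (2,000 trees by default): every tree
     trains on n₁ presences and n₁ pseudoabsences drawn with replacement
     within class; the score is the fraction of trees voting presence.
     Implemented over scikit-learn decision trees with `sqrt` feature
     subsampling.
   - **weighted boosted regression trees**: interaction depth 3, learning
     rate 0.005, 66% bag fraction, pseudoabsence weight 1/12 (8.3%) of a
     presence, tree count selected by 4-fold cross-validated binomial
     deviance up to a 7,500-tree cap. Backed by LightGBM
     (`max_depth=3`, `num_leaves=8`, single-threaded deterministic mode);
     the CV curve is evaluated per tree and growth stops once the deviance
     has not improved for `brt_step_size` trees.
   The **ensemble** score is the arithmetic mean of the two members; no
   calibration is applied. `TrainConfig.fast()` is a reduced-compute profile
   (400 forest trees; learning rate 0.02 with a 1,200-tree cap, preserving
   the rate × capacity product) used by the test-bed studies.
6. **Evaluation.** Leave-one-year-out: all rows dated in the held-out year
   (pseudoabsences assigned by their *own* random dates, so the test side
   represents that year's conditions) are scored by models trained on the
   rest; discrimination is the rank AUC (Mann–Whitney, ties ½). Regional
   validation trains without a region's records, averages the daily
   prediction over the region, groups days into 10-day bins anchored at
   Jan 1 (the last bin keeps the 5–6 remainder days), codes a bin 1 iff at
   least one *raw* (unthinned, unresampled) observation falls in it, and
   reports the point-biserial correlation (Pearson on 0/1 vs mean
   prediction; significance via the t-transform). Years with fewer than 10
   raw records in the region are excluded.
7. **Maps.** Every unmasked cell is scored as if a record sat at its centre
   on the target date; masked cells are NaN, never 0. For display, bilinear
   interpolation on cell-centre nodes refines maps to e.g. 0.02°, with
   nearest-node padding beyond the outermost centres, output clipped to
   [0, 1], and an output cell missing iff any node with nonzero weight is
   missing. Analyses always stay at the working resolution.

## The synthetic test bed

Because the real record streams and reanalysis rasters require external
services, the package ships a generator with *known ground truth*:

- **Weather**: daily, on a configurable lat/lon grid (default 20×20 cells at
  0.25°, seven years). Mean temperature = annual mean (13 °C at the southern
  edge) + latitudinal lapse (−0.8 °C/degree) + seasonal sinusoid (amplitude
  9 °C, peak at day 200) + per-cell AR(1) noise (ρ = 0.7, σ = 2.2 °C);
  tmin/tmax bracket it by ±4.5 °C plus half-normal spread. Precipitation is
  a seasonally varying wet-day process (wetter winters) with gamma
  magnitudes; wind is lognormal; snow grows with frost degrees. These
  choices reproduce the features the models rely on — persistence,
  seasonality, a spatial gradient — not any particular region's climate.
- **Niche**: a product of smooth interval responses on trailing-window
  aggregates. The default is a single condition, 30-day mean temperature in
  [15, 18] °C with 0.3 °C sigmoid edges, giving a 2–3-month season (split
  into early- and late-summer shoulders in the warm south, a single
  mid-summer window in the cool north). Scoring records with the *true*
  suitability yields an AUC of ≈ 0.91 against 12:1 uniform pseudoabsences —
  the irreducible ceiling any model can approach, set deliberately at a
  discrimination level typical of well-sampled insect-phenology datasets.
- **Effort bias**: enters event generation *multiplicatively* with
  suitability — exactly the confound the temporal correction targets.
  Default: weekend ×3, +0.04/°C, −0.10/mm precipitation, −0.25/(m/s) wind
  on the log scale. Benchmark-taxon records use the same effort with
  suitability ≡ 1.

What the test bed does **not** emulate: spatially clustered observers,
holidays, multi-species confusion, coordinate error beyond cell-jitter,
missing weather values at scale. Passing tests therefore demonstrate the
machinery recovers a known niche under known bias, not performance on any
real stream.

## Numerical and design choices

- Cells are half-open, `floor((coord − origin)/cell)`; no spatial
  interpolation of weather to points.
- Pseudoabsence dates are uniform over calendar days (leap years get
  proportionally more mass); a `redraw` policy avoiding the source record's
  exact date exists but is off by default.
- Sub-daily forecast slices aggregate per day as mean (tmean/wind/snow),
  min/max (tmin/tmax) and sum (precipitation); spatial coarsening is a block
  mean, except precipitation which follows the accumulation convention
  (block sum); refinement is nearest-cell.
- One master seed expands into named per-stage seeds through
  `numpy.random.SeedSequence.spawn`, so stages rerun identically in
  isolation; with fixed seeds the evaluation report and the map files are
  byte-identical across reruns.
- Degenerate inputs fail loudly: single-class training sets, perfect
  separation in the effort GLM, all-zero-variance feature sets, regional
  validation with one outcome class (r reported as NaN).

## Problem sizes

The default synthetic study (six modelled years, ~1,500 events, 12:1
pseudoabsences → ~19,000 rows × 56 features) runs the full leave-one-year-out
evaluation in about a minute per dataset variant on one core with the
`fast()` profile; the acceptance script (`scripts/acceptance.py`) completes
its whole set of studies in a few minutes. The full-size training profile
(2,000 forest trees, 7,500-tree boosting cap at rate 0.005) is the default
for real analyses.

## Known limitations

- The effort model omits drivers like holidays and observer density, and is
  purely temporal; spatial effort variation is only addressed by the
  thinning steps.
- Greedy correlation filtering is order-dependent by design; a different
  tie-break yields a different (equally valid) minimal set.
- The boosted-trees member depends on LightGBM's tree builder; exact tree
  counts selected by cross-validation are reproducible for a fixed seed but
  may differ across LightGBM versions.
- Interval niches with multiple interacting conditions are supported by the
  generator but the default study exercises a single axis.
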