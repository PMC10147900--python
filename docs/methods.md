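# Methods

`gridexposure` implements a county-level power-outage exposure analysis as a
reusable, tested pipeline: reliability screening of raw 10-minute outage
feeds, threshold-based outage-event detection with relative (SAIFI-like) and
absolute (SAIDI-like) exposure metrics, rule-based severe weather/climate
event classification with a co-occurrence ratio statistic, and detection of
spatial clusters of dual social/medical vulnerability and outage burden via
bivariate local Moran's I with permutation inference and FDR control.
Because the commercial feed the design is modeled on is not redistributable,
the package ships a synthetic-data generator whose planted ground truth
makes every downstream stage testable.

## The lattice world

Counties live on a rectangular lattice with explicit rook/queen contiguity,
fixed UTC offsets (no daylight-saving modeling) and customer totals equal to
households + business establishments — the exposure denominator throughout.
Real geography, shapefiles and map rendering are out of scope; the lattice
makes adjacency exact and spatial tests enumerable.

## Synthetic outage feeds

Each county's feed is a 10-minute series of customers-without-power counts:

* **Noise floor.** Outside events, counts are uniform integers strictly
  below 0.05% of customers, so percentile-based threshold derivation sees a
  realistic sub-threshold distribution and detection at the 0.1% threshold
  is never triggered by noise. The noise model is a stand-in — the real
  feed's noise structure is not publicly documented — so tests of threshold
  behavior characterize the rules, not the commercial product.
* **Planted events.** Event starts are Bernoulli per county-day, split into
  short (1–7 h) and long (8–24 h) duration classes (default 30% long,
  integer hours, uniform within class). Onset hours follow a discretized
  normal on the local clock, mean 18:00, sd 1.5 h — an evening peak with
  most onsets between 15:00 and 20:00, coinciding with peak load. During an
  event the fraction out is constant, drawn uniformly from [0.2%, 5%].
  Overlapping or touching events in a county are merged (the merge is
  counted in the truth record) so a planted event always equals one maximal
  above-threshold run.
* **Weather coupling.** When a daily flag calendar and relative risks are
  supplied, the probability that a *long* event starts on a county-day is
  multiplied by the relative risk of every event type flagged that day.
  With all risks at 1 the construction is independent by design, which the
  tests verify by chi-square and by ratio calibration.
* **Missingness.** Reporting gaps are i.i.d. dropped 10-minute slots by
  default, with a block-gap mode (contiguous feed dropouts, mean 3 h) to
  stress run-breaking logic. Gap fractions can vary per county to plant
  unreliable counties.
* **Reproducibility.** One master seed feeds a `SeedSequence` hierarchy of
  per-purpose, per-county substreams; regenerating any piece with the same
  seed is bit-identical, and the truth record can be built without
  materializing the streams.

The default simulated problem sizes (10×10 lattices, one-year spans for
feed-level checks; 20×20 lattices for spatial-clustering simulations) were
chosen so each property is tested at a scale where its Monte-Carlo error is
meaningful. County-level spatial simulations use a Poisson shortcut
(`simulate_outage_counts`) for the annual 8+ hour counts rather than full
feeds, since the clustering statistic consumes only per-county counts.

## Reliability screening

A county-year is reliable when (a) the feed reported in ≥50% of the
expected 10-minute slots of the local calendar year (leap-aware) and (b)
the maximum simultaneous customers tracked covered ≥50% of county
customers. Both thresholds are inclusive. Coverage uses the stream's
optional `customers_tracked` column; absent that column coverage is treated
as complete. Counties are tiered by reliable-year count (1+, 2+, all span
years, nested); each analysis stage consumes a configurable tier, the
co-occurrence stage defaulting to the full-span tier and the vulnerability
stage to 2+.

Whether screening should be per-year or whole-span, and how "customers
tracked" is best measured, are genuinely open operationalizations; per-year
assessment matches the tiering language ("2+ years of reliable data") and
is the package's fixed choice.

## Event detection and exposure metrics

Readings aggregate to the county-hour on the local clock. Two statistics
are kept deliberately distinct:

* detection uses the **within-hour maximum** — an outage visible at any
  reading counts, a conservative choice;
* customer-hour integration uses the **within-hour mean** of readings
  (equal weights on the regular 10-minute grid) — an unbiased rectangle
  integral of customers out.

A county-hour is "out" when `customers_out_max / customers_total ≥ 0.001`
(exact fractions, no integer rounding): 100 customers in a county of
100,000, 1000 in a county of a million. The 0.1% default corresponds to the
90th percentile of county-hour fractions in the source data;
`derive_threshold` recovers a percentile empirically (linear interpolation
between order statistics) as a data-driven alternative. Maximal runs of
consecutive out-hours are events; an unreported hour terminates a run
(missingness is never counted as exposure, so gapped long outages may
split — durations are biased short, never long). Durations are counted on
the hourly grid; events are attributed to the calendar year and local clock
of their start hour.

Threshold monotonicity deserves a caveat: for arbitrary series, raising the
threshold can split one long run into several, so event *counts* are not
monotone in general — only total above-threshold time and each event's
duration are. For plateau-shaped events (noise floor strictly below, event
level above), counts are monotone too; the tests check both forms.

Summaries: per county-year counts of 1+ and 8+ hour events over reliable
years only, annual averages dividing by the number of reliable years
(SAIFI-like); customer-hours totals and hours per customer (SAIDI-like);
and a month × local-start-hour matrix of 8+ hour event onsets.

## Weather classification and co-occurrence

Seven daily county-level event types: anomalous heat (temperature > 24 °C
and above the county-week 85th percentile of the climatology baseline),
anomalous cold (< 0 °C and below the 15th percentile), heavy precipitation
(above the county 85th percentile), snowfall (≥ 2.54 cm), lightning (any
flash), tropical cyclone (track center within 100 km, inclusive), wildfire
(≥ 1 km², inclusive). Heat/cold/precipitation bounds are strict
inequalities, matching their wording; cyclone and wildfire are inclusive.
The daily temperature statistic defaults to the table's single daily value
(the generator emits a daily mean); which statistic the source grids should
contribute is configurable upstream of the classifier.

Snowfall days suppress the heavy-precipitation flag by default — snowfall is
separated from heavy precipitation without attempting a water-equivalent
subtraction, which the available inputs cannot support. The precedence is
configurable and off by a flag.

County-days are typed none / isolated (exactly one flag) / multiple (two or
more); multiple-event categories carry a canonical hyphenated label with
types ordered: heavy precipitation, snowfall, anomalous heat, anomalous
cold, wildfire, lightning, cyclone. A county-day is an outage day when at
least one 8+ hour event *began* that local day (same-day starts count
once). The co-occurrence ratio for category *i* is

    (outage days with i / county-days with i)
    ÷ (outage days with no event / county-days with no event),

undefined (not zero) on zero denominators, invariant to common scaling of
all four counts. The tabulation keeps the top-7 multiple combinations by
outage days plus an aggregated Other row (rank configurable). Wind is
excluded as an event type, and no causal attribution of outages to weather
is attempted — co-occurrence is a same-day alignment, nothing more.

`datasets.us_cooccurrence_counts()` bundles the county-day counts of a
published national 2018–2020 US surveillance analysis as worked-example
inputs; ratios are always recomputed from the counts, never stored.

## Vulnerability clustering

Quartiles use linear-interpolation quantile cut points with left-open /
right-closed intervals above Q1; a value tied with a cut point goes to the
lower quartile. The Wilcoxon rank-sum test uses midranks; for pooled n ≤ 12
the null is enumerated exactly (two-sided p = min(1, 2·min(P(W≤w),
P(W≥w)))), otherwise the normal approximation with tie correction applies.

The bivariate local Moran at county *i* is `z(x)_i · Σ_j w_ij z(y)_j` with
x the vulnerability metric (SVI or DME prevalence), y the annual 8+ hour
outage count, row-standardized queen contiguity weights (rook
configurable; islands are excluded), and z-scores using population
(n-denominator) moments — which makes the two-county worked example exact.
The mean of the local statistics equals the global bivariate Moran
statistic; this identity is asserted on every call at 1e-10.

Inference is by conditional permutation: x_i and y_i stay fixed while y is
permuted over the other n−1 locations (sampling k_i distinct values per
permutation by vectorized rejection sampling), and the two-sided pseudo
p-value is the absolute-exceedance rank (count+1)/(m+1), bounded below by
1/(m+1). Fixed seed and permutation count give bit-identical p-values.
Benjamini–Hochberg step-up over all tested counties (the standard "false
discovery rate method" in the LISA literature; BY would be more
conservative than intended) gates the quadrant labels: only significant
counties are labeled high-high / low-low / high-low / low-high.

Two resolution facts shape the simulation designs:

* With m permutations the smallest attainable p is 1/(m+1), while the BH
  rank-1 cutoff is α/n. BH can therefore reject *nothing* unless
  m ≥ n/α − 1. On a 10×10 null lattice with 999 permutations the empirical
  false-discovery proportion is exactly 0 — the FDR check passes by
  construction and is complemented by a pre-FDR rejection-rate-at-α check.
  The planted-cluster simulations on 20×20 lattices use 9,999 permutations,
  the smallest round count clearing the 400-test cutoff.
* Planted dual-burden recovery (3×3 block, SVI +0.4, 20×20 lattice): the BH
  cutoff scales with the number of rejections (≈ R·α/n ≈ 10⁻³), so block
  corners — only 3 of 8 neighbors inside the block — need a strong outage
  contrast to survive. The default planted contrast multiplies the block's
  annual 8+ hour rate (base 2/county-year) by 10, within the span real
  county data exhibits (maxima above 15× the national median). Separately,
  an additive +0.4 shift on a U(0,1) SVI base leaves a member below the
  population mean with probability ≈ 0.11; such counties are genuinely
  low-high, so perfect 9/9 recovery is not the expected behavior and the
  recovery property is stated as ≥7 of 9 members in ≥80% of seeds.

SVI component contrasts (high-high vs all other counties) use Welch
two-sided t-tests on the 16 component percentages; groups smaller than two
are flagged untestable rather than tested.

## Pipeline and I/O

`run_pipeline` chains simulate → screen → detect → cooccur → cluster →
report. All artifacts are plain CSV (UTF-8, ISO-8601, canonical column
order, schema-validated on read with the offending row named) plus JSON for
the truth record and the run manifest (config hash, seed, library versions,
per-stage row counts). Every stage is a pure function of (inputs, config,
seed); identical configs byte-reproduce every output, which the tests check
by file comparison. The report stage rebuilds the co-occurrence ratio table
from stored intermediates without touching raw streams. The `gridexposure`
CLI exposes each stage with a flat TOML config; exit codes are 0/1/2 for
ok / input error / internal error.

## What passing tests do and do not show

The generator emulates intermittent reporting, plateau-shaped planted
events with an evening onset peak, weather-coupled long-event risk and
spatially clustered vulnerability. It does not emulate sub-county feeds,
utility-level structure, drifting customer denominators, within-event
customer churn, seasonally varying weather base rates, spatially correlated
weather, or daylight-saving time. Recovery and calibration results
therefore validate the pipeline's logic and statistics under controlled
conditions; they are not evidence about any commercial data product.

## Known limitations

* Duration is counted on the hourly grid (a 10-minute run-length option
  exists in the generator's truth but detection is hourly); sub-hour
  exposure within a detected hour is not resolved.
* An unreported hour splits events; under heavy missingness detected event
  counts inflate while durations deflate. Screening at the 50% reporting
  rule bounds, but does not remove, this effect.
* The LISA quadrant compares against the sample mean; on small lattices a
  handful of counties near the mean can flip quadrants between seeds.
* Coverage (customers tracked) in the synthetic feed is constant per
  county; real feeds drift.
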