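# Methods

## Scope and data model

The pipeline starts at quantified monthly concentrations: instrument
formats, chromatography and method validation are out of scope. Sampling
timestamps are coarsened to calendar year-months — the campaigns it models
sample each station once a month and publish no day-of-month — so one
observation exists per (station, analyte, month). Concentrations are ng/L,
discharge m³/s, and their product is the mass flow in µg/s exactly
(1 ng/L · 1 m³/s = 1000 ng/s). Reports can relabel to mg/s (÷1000) where a
legacy unit is expected; the source material itself is inconsistent between
the two, and the µg/s identity is the reason it is the native unit here.

Below-LOQ values travel as an explicit censored marker (CSV token `<LOQ`),
never as zero or blank. Truly missing samples (no sampling event) are a
different thing: they stay absent, are never interpolated, and period
averages run over available months only. Only below-LOQ cells are
imputable.

## Censoring substitution

Censored cells are replaced by `fraction × LOQ` with fraction 0.1 by
default — the conventional simple-substitution rule for such monitoring
data. The substituted rows keep an `imputed` flag through the whole
pipeline so reports can state per-analyte imputed fractions.
Distributional estimators for censored data (Kaplan–Meier,
censored-likelihood fits) would be the statistically stronger choice when
censoring is heavy; they are an explicit extension point
(`riverflux.preprocess`), not implemented, because substitution is the rule
the analysis this package operationalises actually uses.

## The loss factor F

For one analyte on one river, station *i* contributes
r_i = L_i(OOL) / L_i(LCK), the ratio of its arithmetic-mean mass flow over
sampled out-of-lockdown months to that over sampled (pooled) lockdown
months. F is the unweighted mean of the r_i over the N eligible stations;
dispersion is the sample (n−1) standard deviation of the r_i, zero when
N = 1. A station is eligible only with at least one sampled month in each
period and a non-zero lockdown mean; exclusions are logged, never silent.
With LOQ/10 substitution active and positive discharge, a zero lockdown
mean cannot occur.

Notes on conventions that were genuinely open:

* **Pooling.** Both lockdown windows form one LCK stratum for F, because
  that is how the loss tables this statistic reproduces are defined. The
  two lockdowns differed in strictness, so per-window factors (each window
  against OOL, other windows' months dropped) are emitted as supplementary
  output (`factor_table_by_window`).
* **Dispersion axis.** The (n−1) standard deviation across stations is the
  default, matching F's own definition as a mean over stations. An
  across-time variant — the SD over OOL months of the cross-station mean of
  L_i(month)/L_i(LCK) — sits behind `stdev_axis="time"` because the source
  description ("the respective standard deviation") does not fully pin the
  axis down.
* **Thresholds.** F ≥ 1.5 flags a substantial loss, F ≥ 2 a more-than-
  halved flux; both are plain comparisons on F, and halved implies
  substantial by construction.
* **Window months.** The default calendar resolves "mid-March–mid-May
  2020" to 2020-03..2020-05 and "late October 2020–March 2021" to
  2020-11..2021-03, leaving 2020-10 out-of-lockdown: the within-month
  sampling date is unknown, and a window that opens late in a month cannot
  claim that month's single sample with any confidence. The calendar is a
  plain YAML input, so any other resolution of the half-month boundaries is
  one edit away.

## Aggregates

Summed series (per river, per category) add member mass flows per month;
station-months that were never sampled contribute 0 and are accounted for
by a completeness fraction carried with every aggregate row, so total
series stay comparable across months without pretending the data exist.
Because the eight therapeutic categories partition the analytes, the
category totals conserve the all-analyte total at every month exactly (to
floating-point); this is asserted in the tests rather than assumed.

## Pattern PCA

The station × month matrix holds each station's panel-summed mass flow; the
category × month matrix sums over member analytes and all stations. Both
are zero-filled for unsampled cells (with the completeness matrix attached
as metadata) to stay rectangular. PCA runs on column-mean-centred data;
unit-variance scaling is off by default since all columns share one unit,
but `standardize=True` is exposed because published explained-variance
figures can depend on that choice. The underlying decomposition is a full
SVD (scikit-learn), with one convention added: each component is oriented
so its largest-magnitude loading is positive, which makes scores files
byte-reproducible across runs and platforms. Degenerate inputs (all rows
identical; zero-variance columns under standardization) are errors, not
silent NaNs.

Cluster rectangles on score plots are human annotation. The package emits
scores, loadings, explained fractions and a Euclidean score-distance
matrix; it does not assign groups.

## Synthetic campaigns

The generator exists because the original campaign's concentrations and
discharges were never publicly released; it emulates the statistical
structure the analysis assumes so that every stage is testable end to end.

* Concentrations: per-analyte log-normal around a baseline geometric mean
  (σ = 0.3 by default, a typical between-month spread for monthly river
  sampling), divided by the analyte's multiplier ρ during lockdown months.
  The effect acts on concentration, not discharge — flow variation is
  exactly the nuisance the mass-flow formulation removes.
* Discharge: per-station base level times a shared annual sinusoid (peak in
  April, amplitude 0.3 — a snowmelt-fed regime) times log-normal noise
  (σ = 0.2). Default bases ramp 250→1200 m³/s downstream on the larger
  river and 300→550 m³/s on the smaller, mimicking rivers that grow from
  tributaries versus ones that do not.
* Censoring: draws below the analyte LOQ become the censored marker.
  Built-in LOQs are evenly spaced over the published 0.2–0.9 ng/L method
  range in catalogue order — a deterministic stand-in, since per-analyte
  LOQs were not published.
* Defaults mirror the studied campaign: 7 + 5 stations, 16 months
  (2020-01..2021-04), the 18-compound catalogue with its per-river panels
  (17/7), baseline geometric means chosen as plausible mid-range values for
  large European lowland rivers receiving urban wastewater, and per-analyte
  ρ set to the published loss factors so the default campaign carries the
  effect sizes the analysis was built to detect.
* Determinism: one `numpy` generator seeded from the config, drawn in a
  fixed site → analyte → month order; the same config yields byte-identical
  CSVs. Replicate seeds in `replicate_f` are spawned from the config seed
  via `SeedSequence`.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: within-month sampling-time variability (one grab
sample per month can sit anywhere in the diurnal/weekly cycle),
between-station correlation of concentrations beyond the shared effect,
serial correlation in discharge, in-sewer or in-river degradation and
travel time, and population-normalised consumption back-calculation.

### A deliberate confounder: discharge seasonality

The ratio r_i divides period means of c·Q, so a seasonal discharge cycle
that is asymmetric between the LCK and OOL month sets biases F away from ρ
even without noise: with the default calendar and amplitude 0.3 the
lockdown months sit in the high-flow half of the year and F is pulled down
by roughly 10%. This is a property of the statistic, not a bug, and the
default campaign keeps the cycle so the bias is visible. Parameter-recovery
measurements (tests and the acceptance script) therefore run with the
seasonal cycle off — recovery of ρ is only defined under discharge
stationary in distribution across periods — while keeping the log-normal
discharge noise, which is stationary. A second, smaller effect is the
Jensen bias of ratio estimators: E[Ā/B̄] ≥ E[Ā]/E[B̄], about +1% at σ = 0.3
with 8 months per period, shrinking as σ → 0.

## Numerical choices

* Period means and per-station ratios are plain float64 arithmetic; in the
  noise-free halved scenario the pipeline returns F = 2.0 *exactly*,
  because the halving is a power-of-two scaling and the period means
  average identical values.
* CSV writers format floats with `%.17g` and the readers parse with
  Python's exact `float()` (the fast C parsers are off by an ulp), so a
  write/read round trip reproduces a campaign field-for-field.
* Factor tables sort by F descending with the analyte name as a stable
  tie-break.
* The covariance/eigendecomposition cross-checks in the tests tolerate
  1e-8; the factor oracle equivalence tolerates 1e-12 relative.

## Registry caveats

The built-in station registry reproduces printed coordinates verbatim,
including one latitude that is geographically impossible (it duplicates a
neighbouring station's longitude — an evident transcription error in the
source). The registry warns about outlier latitudes (> 5° from the river's
median) and accepts per-station overrides; it never corrects published
values silently. The built-in Sava panel carries 17 of the 18 catalogued
compounds because the source reports 17 measured there while cataloguing
18; which compound to drop is not stated, so the default exclusion
(amisulpride) is an arbitrary, documented and configurable choice
(`builtin_registries(sava_excluded=...)`, `None` restores all 18).

## Known limitations

* Substitution-based censoring handling biases low-concentration summaries
  when the censored fraction is large; the imputed-fraction report is the
  guard rail, a censored-likelihood estimator the future fix.
* Stations are independent: no routing, dilution or travel-time modelling
  between them.
* F has no attached significance test — it is a descriptive ratio with a
  dispersion, reproducing the source analysis; uncertainty beyond the
  across-station SD (e.g. bootstrap over months) is future work.
* The published loss tables and the 85.5% two-component variance figure can
  only be reproduced bit-for-bit with the original appendix data, which has
  no public accession; the conditional reproduction test activates if that
  data is placed under `data/appendix/`.
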