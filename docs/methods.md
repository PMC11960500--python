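# Methods

## Data model and ingestion

FAERS quarterly extracts are "$"-delimited ASCII tables. The package reads
four kinds — DEMO (report versions with demographics), DRUG (reported
drugs with role codes), REAC (reactions as MedDRA preferred terms) and
THER (therapy dates) — accepting several header vintages and an extended
synthetic dialect in which DEMO additionally carries `serious` and
`outc_cod` columns (real FAERS stores outcomes in a separate OUTC table,
which is outside this package's scope; when the columns are absent,
seriousness is derived from any serious outcome code present). Malformed
rows and unparseable numeric fields are retained where possible, counted
and logged rather than silently dropped.

Deduplication keeps, for every case id, the version with the maximal
(FDA receipt date, primary id) key — the standard FAERS convention that a
follow-up report supersedes earlier versions — and is idempotent. Drug,
reaction and therapy rows are then restricted to each case's retained
version. Focal-drug cases are those with at least one drug row matching a
configurable name dictionary by case-insensitive substring (FAERS drug
names are free text with salt/biosimilar suffixes) in a configurable role
set, primary suspect only by default.

Ages are converted to years with fixed factors (decade = 10, month = 1/12,
week = 1/52.18, day = 1/365.25 years) and binned into <18, 18–44, 45–64,
65–74, ≥75 (lower bound inclusive: 65.0 falls in 65–74, 75.0 in ≥75).
Time to onset is the day difference between the case-level event date and
the earliest therapy start date of the focal drug; negative differences
(almost always date-entry errors) are excluded from onset summaries with
an explicit count, as are records lacking either date.

## Contingency tables and counting units

Tables are built at PT or SOC level (PT→SOC via an external two-column CSV
or the bundled synthetic vocabulary; unmapped PTs pool under an
`unmapped` pseudo-SOC with a warning). Two counting units are supported
and always explicit, because published analyses mix them: with
`unit="event"` the margins are drug-event pairs (one case may contribute
several events; PT-level convention here), with `unit="report"` each case
contributes at most once per term and the margins are case counts
(SOC-level convention). The package takes no position on which unit is
"correct" — published SOC tables and figures for the same data differ in
unit without comment — so both are first-class.

`reconstruct_from_published(a, ror, drug_total, grand_total)` inverts the
ROR identity to recover the comparator cell, c = round(a·S / (ror·b + a))
with b = drug_total − a and S = grand_total − drug_total. Rounding is
nearest-integer (counts are integers; published RORs for large signals
carry ≥ 6 significant figures, enough for exact recovery); the result is
rejected if its recomputed ROR drifts more than 1% from the input. For the
published aducanumab margins (1,095 focal events; 54,336,884 database
events) this reproduces the printed PRR, IC and observed/expected values
of the strong signals to well within 0.1%.

## Statistics

* **ROR** with the Woolf lognormal CI. A zero cell makes the statistic
  undefined (NaN, which downstream criteria fail) unless the
  Haldane-Anscombe +0.5 continuity correction is enabled.
* **PRR** with the four-cell Pearson χ², uncorrected by default: the
  uncorrected form reproduces published pharmacovigilance χ² values
  (e.g. 14.7 for a 3-count table whose printed value is 14.67); a Yates
  flag exists.
* **IC**: the point estimate is the observed/expected form
  log₂(a·N/((a+b)(a+c))) — exactly log₂(a/E), which is the convention the
  published IC values follow. IC−2SD uses, by default, 10⁵ seeded draws
  from the Dirichlet(a+1, b+1, c+1, d+1) posterior of the cell
  probabilities (sample SD of the IC draws); a closed-form gamma
  approximation in the classical BCPNN style with symmetric unit priors is
  available. A posterior-mean point estimate is offered as an alternative.
  The published IC−2SD values imply a variance convention that is not
  stated in the source and is not reproduced here; the package's own
  conventions are pinned and seeded instead.
* **MGPS**: the two-component gamma mixture prior is fitted by direct
  maximum marginal likelihood (the negative-binomial mixture) using
  multi-start Nelder-Mead on log/logit-transformed parameters, starting
  from DuMouchel's canonical (0.2, 0.1, 2.0, 4.0, 1/3). Gamma parameters
  are bounded to [1e-6, 1e6]: beyond that, gammaln differences cancel
  catastrophically and an optimizer chases floating-point noise. The
  mixture weight is weakly identified when the truth is effectively
  single-component (the fitter may split one gamma into two nearby parts
  with near-identical likelihood); tests of that limit are therefore
  seed-averaged. EBGM is exp(E[ln λ | a]) of the posterior mixture;
  EBGM05 inverts the posterior CDF by Brent bisection (1e-6 relative).
  With few tables (< 10) the canonical prior is used unfitted. Published
  EBGM values equal a/E to ~5 significant figures (negligible shrinkage at
  those counts), so the raw a/E ratio is always returned alongside.

## Signal criteria

All five criteria must hold: a ≥ 3, ROR CI low > 1, PRR ≥ 2 with χ² ≥ 4,
IC−2SD > 0, EBGM05 > 2. Boundary semantics are frozen: count, PRR and χ²
thresholds inclusive, the three interval bounds strict; an undefined
statistic fails its flag. No multiple-testing adjustment is applied (none
is applied in the published analysis this mirrors); with ~30–40 terms and
the conjunction of five tests the family-wise false-positive rate is small,
but users screening thousands of terms should treat flags as hypotheses.

## Stratified, temporal and onset analyses

Stratified runs restrict *both* margins (focal and comparator) to the
stratum — the standard subgroup-disproportionality convention that removes
stratum-level confounding. Strata combine sex, age group, report-year
period and seriousness filters; terms with a < 3 are reported flagged
low-count; records with unknown sex/age are retained in totals and fall
out of the corresponding strata.

The temporal analysis is cumulative-through-year by default (statistics at
period t use all reports with receipt year ≤ t), matching the
progressive-accumulation reading of surveillance heat maps; a
non-cumulative per-period mode exists. Terms with a = 0 in a period carry
NaN missing markers. The final cumulative period equals the full-data
analysis exactly.

Onset summaries use linear-interpolation (type-7) quantiles and the
conventional day bins 0–30, 31–60, 61–90, 91–120, 121–150, 151–180,
181–360, >360, inclusive at both printed endpoints with day 0 in the first
bin.

## Synthetic data generator

The generator emits the four FAERS tables with controlled structure:
background term frequencies over a bundled ~40-PT vocabulary spanning the
22 standard SOCs; focal reports drawing terms from the background
frequencies multiplied by per-term implanted relative risks
(renormalized); per-category demographic probabilities; independent
per-outcome Bernoulli flags; truncated-normal weights; a parametric or
empirical time-to-onset distribution; and a configurable fraction of cases
emitted twice with distinct version keys to exercise deduplication. All
randomness flows from one integer seed through numpy Generator streams in
a fixed order; output files are byte-identical across runs, and category
dictionaries are serialized in insertion order because draw order is part
of the determinism contract.

The calibrated profile (`aducanumab_profile`) sets every demographic
category probability to the published marginal proportion of the 510 FAERS
aducanumab reports, weight to normal(71.49, 16.36) truncated to
[34.2, 132.0] kg, events-per-report to a truncated geometric with mean
1095/510 ≈ 2.15, onset availability to 217/510, and implanted relative
risks that emulate the ordering and rough magnitude of the strongest
published signals at desk scale.

Deliberate departures from realism, and hence limits on what passing tests
show about real FAERS data:

* **Desk-scale background rates.** ARIA-type terms get ~10⁻³ background
  probability instead of the real ~10⁻⁶, and the default background corpus
  is 10⁵ reports, not 18 million. Real RORs of ~5·10⁴ are therefore not
  reproduced by simulation — that regime is covered instead by the
  reconstruction route, which uses the published margins directly.
* **Empirical onset distribution.** The published onset histogram is
  non-monotone (a dip at 31–60 days, a bump at 151–180) and no
  two-parameter Weibull or lognormal tracks it bin by bin (best binned-MLE
  Weibull is off by ~9 percentage points in one bin). The profile
  therefore samples the printed histogram directly (piecewise-uniform
  within bins, the open >360 bin closed at 720 days); Weibull and
  lognormal families, fitted to binned data by maximum likelihood, remain
  available, and the binned-MLE fitter is exposed for comparison. The
  binned profile's implied median (~135 days) is close to but not exactly
  the published 146 days, which is an empirical median the bins alone
  cannot pin down.
* **No dependence structure.** Events within a report are iid draws, PT
  co-occurrence is unmodelled, seriousness and outcome flags are
  independent of each other and of demographics, and drug names contain no
  misspellings. Only the published marginals are calibrated.

## Simulation designs used in the checks

* MGPS parameter recovery uses 5,000 (a, E) pairs with E ~
  Exponential(mean 15) + 0.5: exposures informative enough that the MLE's
  own sampling error stays within the 25% recovery band (with mean-5
  exposures the estimator's sampling error on the second shape parameter
  can exceed it for some realizations).
* ROR CI coverage uses two-binomial sampling (500 exposed at odds ratio 3
  versus 5,000 comparators at risk 0.08, 2,000 replicates), where the
  Woolf interval is expected to be near-nominal.
* Implanted-signal recovery runs the full generate → ingest → statistics →
  criteria pipeline on the default 10⁵-report corpus with one term at
  relative risk 50, over 20 seeds; null calibration repeats it with no
  implants.

## Problem sizes and runtime choices

Simulation-based tests use corpora of 3·10³–10⁵ reports, 10³–10⁵
Monte-Carlo draws and 5–50 replicates; these sizes were chosen so the full
suite completes in minutes on one CPU while keeping every statistical band
well-resolved. The acceptance script's targets are deterministic
reconstructions and run in well under a second.
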