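# Methods

## Scope and data model

carbrisk operates strictly downstream of peak integration. Its inputs are
tabular: calibration series (nominal concentration, analyte peak area,
internal-standard peak area, medium), blank-signal replicate sets,
spike-recovery replicates with day labels, per-sample residue tables
(sample × pesticide × μg kg⁻¹ with non-detect flags), an MRL table, chronic
oral reference doses, and consumer exposure profiles. Residue tables are
plain pandas DataFrames with a fixed CSV schema (`sample_id, pesticide,
concentration_ug_per_kg, detected`); non-detect concentrations are blank.

## Calibration and detection limits

Relative response (analyte/IS area ratio) is regressed on nominal
concentration by unweighted OLS. The survey design spans five decades
(0.001–500 μg kg⁻¹) with no stated weighting, so unweighted is the default
and a `1/x` weighting is available but off. A flat response across distinct
concentrations yields slope 0 and an explicit `informative=False` flag
instead of an error; quantification then refuses. Back-calculated
concentrations below zero — legitimate near the blank — clamp to 0 with a
`below_range` flag, and values outside the fitted range carry an
`extrapolation` flag.

LOD/LOQ derive from blank statistics: with `S_m = S̄_bl + k·σ_bl`, the
minimum concentration is `c_m = (S_m − S̄_bl)/m = k·σ_bl/m` (k = 3, 10).
Some method write-ups simplify this inconsistently to `k·S̄_bl/m`; that
literal variant is retained behind `formula="literal"` for auditing
reports computed that way, but the default follows the derivation and the
S/N ≥ 3 / ≥ 10 convention. Blank SD uses the sample (n−1) denominator:
twenty blanks are a sample. A forced consequence of the shared formula is
LOQ = (10/3)·LOD exactly, which the tests assert as an identity.

## Matrix effect

The slope-ratio definition only: `ME% = 100·(m_matrix − m_solvent)/m_solvent`.
The ±20 % boundary is classified inclusive-soft (values from −20 to +20 are
negligible; strictly outside is significant). Assessment consumes two fitted
curves, not raw series, so the fit policy lives in one place. Per-level
matrix factors and post-column infusion variants are out of scope.

## Validation statistics

Recovery uses the grand mean of replicates at a level. RSD is sample-SD
based. Intraday RSD is reported per day plus a pooled within-day figure
(pooled variance over day groups); interday RSD is computed over all
replicates pooled across days — the natural reading of a
"12 replicates (6 analyses per day)" design — with a mean-of-daily-RSDs
mode switchable, and a between/within one-way ANOVA decomposition available
as a diagnostic only. Acceptance windows (recovery 60–140 %, every reported
RSD ≤ 20 %) are inclusive at the boundaries, and the flags are pure
functions of the computed statistics.

## Measurement uncertainty

Top-down from validation data, per analyte and spike level (the two levels
are never pooled). Relative bias per replicate is (measured − true)/true;
its mean and *population* SD combine into `u(bias)` exactly as the
estimator is defined — the one place a population denominator is used, kept
deliberately distinct from the sample-SD convention elsewhere.
`u(precision)` is the intermediate-precision (interday) RSD as a fraction;
intraday is available via `precision="intraday"`. All internal quantities
are fractions; only the expanded uncertainty `U = 100·k·u` is a percentage,
which prevents the %-vs-fraction mixing these formulas invite. k defaults
to 2 (≈ 95 % coverage); compliance is `U ≤ 50 %` inclusive.

## Residue screening

Summaries are computed over detected samples only, because survey
distribution tables report detect-only ranges; percentages are relative to
the full sample count and kept at full precision, with one-decimal rounding
applied only at display. Both SD and SE (= SD/√n_det) are reported, since
published "± dispersion" columns are frequently standard errors — the
mapping is left to the reader. MRL exceedance is strict (`> MRL`): the
regulatory convention, and the boundary case never occurs in the fixture so
it had to be decided here. Screening is order-independent and idempotent.

## Monte-Carlo risk assessment

Concentration is the only stochastic input; IR and BW are profile
constants. The lognormal is parameterised by arithmetic-moment matching
(`σ² = ln(1+s²/m²)`, `μ = ln m − σ²/2`); log-space moment matching is an
alternative mode. Draws are in μg kg⁻¹ and converted to mg kg⁻¹ inside the
CDI step — the single place units change. The per-pesticide risk metric is
the empirical 95th percentile of HQ using the linear-interpolation quantile
(numpy `method="linear"`), stated so results are bit-reproducible under a
seed. HI is the sum of per-pesticide p95 HQs; the (more conservative)
95th percentile of the per-replicate HQ *sum* is emitted as a clearly
separate diagnostic. Pesticides without an RfDo are excluded from HI with a
warning. A closed-form oracle, `exp(μ + z₀.₉₅σ)·10⁻³·(IR/BW)/RfDo`, backs
every simulated p95 in the tests; at 100 000 replicates the two agree
within 1 % for σ ≤ 1.5. With common random numbers across profiles every HQ
scales by exactly `(IR_c/BW_c)/(IR_a/BW_a) ≈ 1.4290`, so the child/adult HI
ratio is deterministic.

### Choice of dispersion for the survey fixture

The survey's distribution table prints "mean ± dispersion" values an order
of magnitude smaller than its own min–max ranges would imply for a sample
SD. Three readings are implemented: the printed value as SD (`"printed"`),
as a standard error (`"se"`, SD = value·√n_det), and a range-implied SD
(`"range"`, (max−min)/4, the normal-range heuristic). Checked against the
closed-form HI oracle, the range-implied reading reproduces the survey's
published hazard indices to within ~5 % (adult 0.00547 vs 0.00524, child
0.00782 vs 0.00749), while the printed-as-SD and SE readings give roughly
half those values; `"range"` is therefore the fixture default. The per-
sample concentrations behind the published numbers are not deposited, so
exact reproduction is not attempted — the safety conclusion (HI < 1) holds
under every admissible reading, and that bound is what the acceptance
script checks.

## Synthetic-data generator

The generator emulates: lognormal per-pesticide residue distributions with
configurable detection frequency and left-censoring at the LOD; linear
calibration responses with a multiplicative matrix-effect slope
perturbation and additive Gaussian noise on the relative response; Gaussian
blank signals (default n = 20); and spike replicates with configurable
relative bias and RSD in a days × replicates layout (default 2 × 6).
Detection is Bernoulli thinning independent of concentration — a
simplification: real detection probability rises with concentration.
Censoring defaults to `"censor"` (draw, then mark < LOD as non-detect),
which is how survey detection frequencies arise; `"truncate"` (redraw until
≥ LOD) guarantees the nominal detection count. All randomness flows from
one seed through named CRC-keyed `SeedSequence` substreams, so any stage
can be regenerated alone and identical seeds give byte-identical outputs.

What passing tests on synthetic data do *not* show: real residue data have
correlated pesticides within samples, concentration-dependent detection,
heteroscedastic calibration noise, and day effects in precision — none of
which the generator models. The tests demonstrate that the statistics are
computed correctly, not that the survey's field conditions are re-estimated.

## Problem sizes and numerical choices

The fixture survey is 55 samples × 14 pesticides, matching the study
design. Risk simulations use 100 000 replicates (seconds on one CPU);
convergence checks in tests use 10⁴–10⁵ draws with tolerances set by
Monte-Carlo standard error (2–3 SE bands, or the 1 % oracle-agreement
bound). The empirical-quantile method, SD denominators (sample everywhere
except the bias population SD), boundary inclusivity (±20 % ME, 60/140 %
recovery, 20 % RSD, 50 % MU), and strict MRL exceedance are all fixed and
tested so that a given seed reproduces every number exactly.

## Known limitations

No carcinogenic (slope-factor) or acute (ARfD) assessment; no
between-laboratory reproducibility component; no cumulative
(common-mechanism) MRL logic; no bottom-up uncertainty budget; no raw
chromatogram handling. Linear dynamic-range trimming per analyte is left to
the user — the fitted range is recorded from the data supplied.
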