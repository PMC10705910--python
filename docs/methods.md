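# Methods

## Spectrum representation and ion matching

Spectra are nominal-mass EI peak lists: integer m/z with relative
intensities in % of the base peak.  All library I/O normalizes to base peak
= 100 % (idempotent; loss-free for the stored pairs to 4 decimals on a
write/read round trip).  The default matching tolerance is 0.5 Da, which on
a unit-mass grid is equivalent to exact integer matching; it is exposed for
callers with centroided non-integer data.  Ion channels printed as slashed
pairs (129/133, 205/204, 361/359, …) are a single `IonKey` with alternates
constrained to ±4 Da of the primary mass; when both masses appear in one
spectrum the primary wins, and two *distinct* peaks hitting one slot raise
an error instead of being silently merged — the key set, not the data, is
what needs refining in that case.

Missing ions are NaN cells in the matched table.  Pairwise correlation uses
pairwise-complete ions only, so a missing cell removes that ion for the
affected pair alone (this mirrors running the comparison "with and without"
a contested ion such as m/z 205 by passing an explicit exclusion list).

The bundled metabolite inventory preserves the source table verbatim,
including its typographic quirks ("Isocitric asid lactone", "Aukubin",
"Clycerol", a dotted retention time "12.53" and the out-of-range "26:70");
the parser therefore accepts both `min:sec` and decimal-minute retention
times and does not range-check seconds.

## Correlation assignment and the ambiguity verdict

Assignment scores are plain sample Pearson correlations of relative
intensities over the shared ion set (signed r is kept internally; reports
carry |r|, since anticorrelated spectra are as informative as correlated
ones for rejection).  At least three pairwise-complete ions are required
and constant intensity vectors are refused by name.  Ranked candidates that
share fewer than three ions with the query are kept in the output marked
"not comparable" rather than dropped.

A ranking is flagged ambiguous when the top two |r| differ by less than a
configurable gap, default 0.05.  The default is motivated by the observed
situation the toolbox exists for: competing deoxy-sugar standards whose |r|
to the unknown differ by ~0.046 — close enough that correlation cannot
decide, and the verdict must come from the dispersion analysis instead.

## ANOVA, Bonferroni and the statistical screens

Group summaries use sample standard deviations (denominator n−1); the
printed se = sd/√n identity confirms that convention and it is adopted
everywhere outside the scan-window moments (below).  The two-group one-way
ANOVA decomposes SS_model = Σ nᵢ(x̄ᵢ−x̄)² against SS_error = Σ (nᵢ−1)sdᵢ²
with df = (1, n₁+n₂−2); a zero error sum of squares with unequal means is
reported as F = +∞, p = 0 rather than an exception.  With exactly two
groups the Bonferroni family contains one comparison, so the simultaneous
interval degenerates to the unadjusted t-interval on the pooled mean-square
error — this reproduces the published interval limits to the printed
precision.  F and t tail probabilities come from scipy's incomplete-beta
routines.

Shapiro–Wilk delegates to scipy (Royston's AS R94 approximation, valid for
3 ≤ n ≤ 5000); the suite pins it against an independent R `shapiro.test`
value frozen from the same sample.  The probability plot is summarized
numerically: Pearson correlation of the order statistics against Blom
plotting-position normal quantiles ((i−3/8)/(n+1/4)), plus indices of
points whose standardized residual from the fitted line exceeds 2 (the
threshold is an argument).  Cochran's C = max(sᵢ²)/Σsᵢ² is compared with
the critical value [1+(k−1)/F_{1−α/k}(df,(k−1)df)]⁻¹ at the groups' average
degrees of freedom — scipy has no Cochran test, so the critical value is
computed from the F quantile directly.  The KS test requires a fully
specified continuous distribution; fitting-then-testing on the same data is
deliberately not offered.

## Dispersion equations

Scan-window moments are population moments (1/n): the dispersion is the
fluctuation average over the acquired window itself, not an estimate of a
wider population — this is a deliberate contrast with the (n−1) convention
of the chemometrics module and is the reason both conventions are spelled
out at the API boundary.

D″_SD = 2.6388×10⁻¹⁷·(⟨I²⟩−⟨I⟩²).  The companion D′_SD divides the variance
by the squared per-scan deviation (I_j−⟨I⟩)²; that expression is
elementwise, so the implementation evaluates it per scan and aggregates
with a mean by default (a sum reducer is an option).  The mean keeps D′
finite and on the same scale as D″.  Scans exactly at the mean have an
undefined term and are excluded with a warning count; a series whose every
scan equals the mean is an error.  The peak weight A is undefined by any
published convention available here, so it is a user-supplied input with
default 1, never guessed.  The two scale constants are named module
constants whose 2× relationship is asserted in the tests.

D_QC multiplies the ratio of frequency products (3N ground modes over 3N−1
saddle modes — one mode is the reaction coordinate) by exp(−ΔH‡/RT), with
R = 8.31446 J/(mol·K).  Accumulation is in the log domain, so large mode
counts cannot overflow; the tests verify identity with the direct product
up to 10 modes at 1e-12 relative and against an interleaved-ratio route at
60 modes.  Frequencies carry an explicit unit tag (cm⁻¹ or s⁻¹) per vector;
mismatched tags are an error, never a silent conversion — the product ratio
is unit-consistent only within one tag.

The pairwise coupling of two ions' scan series is implemented in two modes.
The default "covariance" mode reads the relation as a cross-dispersion:
r_lm from 2.6388×10⁻¹⁷·cov(l,m) = r·2.6388×10⁻¹⁷·sd_l·sd_m, which is
self-consistent (l = m gives exactly 1).  The literal printed sum form
(D″_l+D″_m)/(sd_l·sd_m) is preserved behind `mode="as_printed"` for
auditability; it is dimensionally odd (l = m yields 2×2.6388×10⁻¹⁷) and the
covariance reading is the package's interpretation, flagged as such.

I_theor = 2.6388×10⁻¹⁷·√D_QC.  The proportionality is defined only up to an
instrument response factor, so theoretical intensities are compared with
experiment in correlation, never on absolute scale.

SineSqr sweeps (y = offset + A·sin²(π(x−phase)/period) against collision
energy) are fitted by Levenberg–Marquardt (lmfit) with a multi-start grid
over the period — the one parameter with troublesome local minima; the
best-RSS start wins and total non-convergence raises with the best RSS
attached.  A constant response short-circuits to the exact degenerate fit
(A = 0, RSS = 0).  The amplitude ratio feeds the indirect dispersion
estimate D″ ≈ 2·(A_D/A_I)·⟨I_TOT⟩.

## Kinetics

Exponential fits y = a·e^{bx} initialize from the log-linear regression of
ln y (falling back to (max y, 0) when y is not strictly positive) and
refine by Levenberg–Marquardt.  χ²/DoF uses DoF = n_points − 2 (points
minus fitted parameters — the standard reading; the source's own DoF
wording is garbled and was not followed).  Fits are unweighted by default
because no replicate variances are available; weights are accepted.  The
surface over pulse frequency is fitted independently per frequency — a
joint 2-D model is a plausible alternative reading, and the per-frequency
choice is labelled an interpretation.  Frequencies with fewer than three
time points are skipped and reported, not fatal.  Residual diagnostics test
against Normal(0, s) with s estimated from the residuals; residuals at
machine precision are reported as a perfect fit rather than KS-tested as a
distribution, and single-residual-DoF fits carry a `low_dof` flag.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every test:

- `gen_spectrum_pair` plants a Pearson correlation by exact Gram–Schmidt
  mixing of standardized vectors, then maps onto intensities by a
  clipping-free affine transform into (11, 99) % before base-peak
  normalization — both steps preserve correlation, so the planted r
  survives to machine precision (the ±0.02 contract absorbs rejection-path
  edge cases).  The default regime in the pipeline (r = 0.9489 over 15
  ions) mirrors the correlation scale at which real carbohydrate
  assignments become contentious.
- `gen_scan_series` targets first and second moments only; the gaussian
  mode refuses sd > mean/3 because truncating at zero would otherwise
  distort the planted moments, and the poisson-like mode (scaled Poisson
  with scale var/mean) is nonnegative by construction.
- `gen_qc_species` draws frequencies uniformly in the physical 50–4000 cm⁻¹
  fundamental band and solves ΔH‡ so the dispersion hits its target
  exactly, refusing targets outside |ΔH‡| ≤ 500 kJ/mol; a zero-enthalpy
  variant solves a commonly-scaled saddle copy instead.
- `gen_concentration_grid` follows the planted exponential law per
  frequency with additive Gaussian noise floored at zero and requires an
  untreated ω = 0 control; the demonstration grid plants the 8.75-fold
  treated/control ratio at 72 h.
- `gen_group_data` matches sample mean and sd exactly by affine
  post-standardization, making the ANOVA-equivalence tests deterministic
  rather than approximate.

Each generator draws from its own RNG stream (`default_rng([kind_id,
seed])`), so adding a generator never perturbs existing fixtures.

What passing tests therefore show: the implementations recover planted
truth under idealized noise (Gaussian or Poisson-like, independent scans,
exact exponential laws, no drift).  What they do not show: robustness to
chromatographic co-elution, detector saturation, retention-time drift,
heteroscedastic replicate structure, or isotope interference — none of
which the generators emulate.

## Problem sizes and numerical choices

The default demonstration and test sizes — 1000-scan series, 15-ion
spectrum pairs, 100-seed recovery sweeps, 100-replicate bias checks on
20-point curves, 6-species dispersion sets — were chosen so each planted
parameter sits well inside its own sampling band (e.g. the scan-variance
check uses the 3·√(2/(n−1)) band of a sample variance) while the whole
suite stays interactive.  Reports are canonical JSON (sorted keys, no
timestamp), so a fixed config and seed reproduce a pipeline report
byte-for-byte.

## Known limitations

- Correlation-based assignment is only as good as the shared ion set; with
  four common ions dominated by the m/z 73 base peak, |r| > 0.99 against
  several candidates is expected and the ambiguity flag, not the top |r|,
  is the meaningful output.
- The dispersion→structure step consumes vibrational frequencies and
  activation enthalpies as *input*; no electronic-structure computation is
  performed or validated here.
- Retention times are carried as metadata only; there is no chromatogram
  alignment, deconvolution or profile-mode support.
- The Bonferroni machinery covers the two-group case the workflow needs;
  multi-group families and FDR control are out of scope.
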