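# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Psychometric fit

Identification trials are modeled as independent Bernoulli draws with
p(HEAD | x) = 1/(1 + exp((x − x₀)/s)) on the continuum step index
x = 1…11. Fitting maximises the Bernoulli likelihood over raw trials
(aggregated internally to per-step counts, which is an identical
likelihood), not least squares on proportions: the ML estimator is well
defined for unequal trial counts per step and has no ad-hoc weighting.
No lapse or guess parameters are included — the boundary width is
defined as the 25–75 % crossing distance of a curve spanning 0–100 %,
and lapse parameters would change those crossing semantics.

The x-axis is the step *index*, not Hz: the width is reported in
continuum steps even though the continuum's steps are not equally spaced
in Hz (the synthetic continuum reproduces the denser interior spacing,
but spacing never enters the fit).

Numerics: L-BFGS-B with an analytic gradient, box constraints
s ∈ [0.01, 50] steps and x₀ ∈ [−5, 17], three deterministic starting
points (empirical 50 % crossing with s = 0.5; continuum midrange with
s = 1; count-weighted mean step with s = 2). Best likelihood wins; ties
within 1e−9 go to the smaller s. The fit is therefore deterministic
given the data. Reversed response coding is handled by also fitting the
flipped-response model and keeping the higher-likelihood orientation, so
boundary and width are invariant to coding. A boundary outside [1, 11]
sets an extrapolation flag. Width = 2·s·ln 3 in closed form; a
root-finding inversion of the fitted curve is kept as an independent
cross-check and agrees to better than 1e−9.

Degenerate inputs (all responses one category, fewer than two distinct
steps) raise typed errors rather than returning a boundary at a bound.

## Production measures

All production statistics use (F1, F2) in mel. The default mel formula
is 2595·log₁₀(1 + f/700), the most common convention in phonetics
tooling; the 1127·ln(1 + f/700) variant is selectable
(`mel_formula_id`) and differs only by floating-point rounding. The
onset window is 0–50 ms absolute; the midpoint window is the middle
50 % of token duration. Window membership is closed at both ends. A
token whose midpoint window would start before 50 ms (duration
< 200 ms) can be flagged as window-overlapping; overlap is flagged,
never auto-excluded. A configurable participant-level flag
(`overlap_duration_ms`, default 150 ms) additionally marks participants
whose mean /ε/ duration is short; the geometric flag and the duration
threshold are reported side by side without asserting that either is
the "true" criterion, because the two do not coincide.

**Contrast distance** is the Euclidean distance between per-vowel mean
midpoint formants, natural-log-transformed. **Ellipse area** is
π·q·√det S with S the n−1 sample covariance of one vowel's midpoint
tokens and q the χ²(2 df) quantile at the coverage level (5.991 at the
default 0.95). This is the *coverage* (data) ellipse of the token
distribution, not the standard-error ellipse of the mean: the measure
is trial-to-trial dispersion, and a standard-error ellipse would shrink
with n and stop measuring it. The coverage level is configurable if the
alternative reading is wanted. The per-participant measure is ln of the
arithmetic mean of the two per-vowel areas. Note the area's units are
mel², although descriptive tables in this literature sometimes print
the unit as mels.

**Centering** uses per-vowel medians as the reference point while the
centroid and ellipse use means; this asymmetry is deliberate and
matches the definitions of the respective measures. Per token,
d_init = ‖(F1,F2)_init − median_init‖, d_mid likewise at midpoint, and
centering = d_init − d_mid (positive = inward, toward the median). Per
vowel, ratio = mean(centering)/mean(d_init) = 1 − mean(d_mid)/mean(d_init);
the participant's centering ratio is the mean of the two vowel ratios.
The ratio is ≤ 1 by construction, with equality iff every d_mid = 0.
Tokens flagged as excluded (tracking failures) are dropped before all
medians, means and covariances; exclusion counts are carried through to
the run record.

Log transforms use the natural log throughout; the base is a
documented convention, fixed so that reported descriptives are
comparable across runs.

## Cohort screening and inference

Shapiro–Wilk tests (scipy's implementation of the standard published
algorithm) are reported per measure over the full cohort. Outlier
screening is a single-pass MAD rule: participant excluded iff
|value − cohort median| > k·MAD for any screened variable, with k = 2.
The MAD is scaled by the 1.4826 normal-consistency constant by default
(the convention of R's `mad()`), making the default cut a 2σ-equivalent
rule that excludes ≈ 5 % per variable under normality; the raw MAD
(constant = 1.0) is one configuration flag away. The cut is strict
(a deviation exactly equal to k·MAD is retained), computed once on the
full cohort (no iterative re-screening), and cohort-wide: a participant
flagged on any variable is removed from all analyses, with the
triggering variables recorded per participant. The screened variables
default to boundary width, log contrast distance and log ellipse area;
the centering ratio is normality-tested but not screened. At a cohort
size near 37 the MAD itself is noisy, so the realised number of
exclusions varies considerably from cohort to cohort even under a
well-behaved generator; the run record always reports the count and the
per-variable overlap.

Inference is three Spearman rank correlations (labeling consistency
against each production measure): Pearson correlation of mid-ranks with
average ranks on ties, two-sided p from the t approximation with n − 2
degrees of freedom. P-values are reported unadjusted; the report notes
that the three tests are related and readers should weigh multiplicity
themselves.

## Synthetic cohorts

The generator exists so that every stage has data with known ground
truth. It emulates the study design it targets: 45 production tokens
per vowel, an 11-step identification continuum presented 20 times per
step, cohorts of 37.

*Listeners* respond with the same logistic model the fit assumes, with
true (x₀, s) per listener. *Speakers* draw a per-token onset deviation
δ ~ N(0, Σ_onset) in mel; onset formants are mean + δ and midpoint
formants mean + (1 − g)·δ + ε, ε ~ N(0, Σ_noise). The correction gain
g ∈ [0, 1] is this package's formalisation of centering: it is the
simplest linear mechanism whose population centering ratio equals g in
the noiseless limit (and exactly g even against sample medians, since
medians commute with the linear shrinkage). The continuum design
mimics a 41-point equally spaced grid from which 11 steps are selected
with denser sampling in the middle 50 %, so interior Hz gaps are
smaller than endpoint-adjacent gaps.

Population defaults were chosen once so that a simulated cohort's four
measures span realistic adult-female ranges for this contrast: vowel
bases /ε/ (630, 2300) Hz and /æ/ (830, 2080) Hz converted to mel, with
25 mel between-participant centroid jitter; per-token onset SD uniform
in 15–30 mel per formant (isotropic, with a small per-vowel multiplier);
midpoint noise SD 0.35 of the onset SD; gain uniform in 0–0.3; listener
scale s lognormal with mean ≈ 0.86 and SD ≈ 0.25 steps (clipped to
[0.3, 1.6]), boundary N(6, 0.7) clipped to [3, 9]; durations
N(179, 25) ms for /ε/ and N(237, 30) ms for /æ/, truncated at zero and
used only by the overlap flag. Dependence between listener width and
speaker dispersion is imposed through a Gaussian copula on parameter
ranks (latent correlation 2·sin(π·ρ/6) for target rank correlation ρ),
so coupling = 0 gives exact independence for null simulations and
positive coupling gives power/sign checks.

What the generator does **not** emulate: real formant-track dynamics
(tracks, when requested, are piecewise-linear in mel and exist only to
exercise the windowing code), formant-tracker failures (exclusion flags
must be planted by the caller), non-Gaussian token dispersion,
within-session drift or fatigue, lapses in the identification task, and
any somatosensory contribution to self-correction. Passing tests
therefore demonstrate the pipeline's correctness and calibration under
a clean generative model, not the field validity of the measures on
real recordings.

## Problem sizes used in validation

The validation suite uses: 200 simulated listeners per condition for
width recovery (at 200 and 20 presentations per step); 100 random
parameterisations for the closed-form/numeric width agreement; 10,000
Gaussian draws for ellipse area and coverage; 45 tokens/vowel for
centering-gain recovery; 100 random tie-free vectors for the rank
statistic; and 2000 independent 31-participant cohorts for the type-I
error of the three tests. These sizes put Monte-Carlo error comfortably
below the tolerance being checked while keeping the whole suite a
few-minute, single-CPU run.

## Known limitations

- The pipeline consumes window-averaged formants (or idealised tracks);
  formant estimation itself (LPC, tracker settings, manual correction)
  is upstream and out of scope.
- The logistic has no lapse rate, so a listener with occasional
  attention lapses will be assigned a slightly wider boundary than an
  ideal-observer analysis with lapses would give.
- With only two vowels, the contrast distance conflates F1 and F2
  differences into one number; no directional information is kept.
- The MAD screen's exclusion count is itself a noisy statistic at
  n ≈ 37 (see above); comparisons of exclusion counts across datasets
  should not be over-read.
- Correlation p-values rely on the t approximation, adequate at
  n ≳ 20 but approximate below that.
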