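# vowelspace

Analysis pipeline for the relationship between speech perception and
speech production at the level of individual differences, built around
the American English /ε/–/æ/ ("head"–"had") contrast.

**Who it is for.** Speech scientists who have (a) a perceptual
identification table — each row one trial in which a listener labeled a
step of an 11-step "head"→"had" continuum — and (b) a production table —
each row one vowel token with first/second formant (F1, F2) means over an
onset window and a midpoint window, in mel. The pipeline computes one
perceptual and three production measures per participant, screens the
cohort for outliers, and tests whether perception and production covary
across people. A synthetic-cohort generator with known ground truth makes
every stage testable without access to raw recordings.

## The measures

For listener responses on continuum steps *x* = 1…11, the probability of
a HEAD response is fit by maximum likelihood with a 2-parameter logistic

> p(HEAD | x) = 1 / (1 + exp((x − x₀)/s)),

decreasing toward the HAD end. The **categorical boundary** is x₀ (the
50 % point) and the **categorical labeling consistency** is the boundary
width — the distance in steps between the 25 % and 75 % points of the
fitted curve, equal to 2·s·ln 3. Smaller width = more consistent
labeling.

Per participant, from (F1, F2) in mel:

- **Vowel contrast distance** — Euclidean distance between the two
  vowels' mean midpoint formants, natural-log-transformed.
- **Area of the ellipse** — area of the 95 % coverage ellipse of each
  vowel's repeated midpoint tokens, π·χ²₂(0.95)·√det S with S the sample
  covariance; the measure is ln of the mean of the two per-vowel areas.
- **Centering ratio** — within-utterance self-correction: per token,
  d_init and d_mid are the distances of the onset- and midpoint-window
  formants from the per-vowel medians; centering = d_init − d_mid.
  Per vowel, mean centering is normalised by mean d_init and the two
  vowels are averaged. 1 = complete correction toward the median,
  0 = none, negative = outward drift.

Cohort screening removes any participant whose boundary width, log
contrast distance, or log ellipse area falls more than 2 MADs (scaled by
the 1.4826 normal-consistency constant, as in R's `mad()`) from the
cohort median. The analysis proper is three Spearman rank correlations
of labeling consistency against each production measure, with two-sided
p-values from the t approximation on n − 2 degrees of freedom.

## Worked example

Simulate a 37-participant cohort, analyze it, and print the report
(every step is also available as library functions):

```sh
vowelspace simulate --n-participants 37 --seed 3 --out sim/
vowelspace analyze --production sim/production.csv \
    --identification sim/identification.csv --out run/
vowelspace report run/
```

The report for this seed ends with:

```
Descriptive statistics (included participants):
  measure                      mean       SD      min      max
  labeling_consistency        1.683    0.512    0.742    2.696
  log_contrast_distance       5.281    0.176    4.935    5.632
  log_ellipse_area            9.070    0.351    8.312    9.824
  centering_ratio             0.081    0.084   -0.102    0.219

Spearman correlations (p-values unadjusted; three related tests are
reported together):
  labeling_consistency x log_contrast_distance: rho(df = 30) = -0.019, p = 0.919
  labeling_consistency x log_ellipse_area: rho(df = 30) = -0.072, p = 0.696
  labeling_consistency x centering_ratio: rho(df = 30) = -0.039, p = 0.831
```

Read: 32 of 37 simulated participants survived screening; their mean
boundary width was 1.68 continuum steps; and, because this cohort was
generated with zero coupling between listener and speaker parameters,
none of the three correlations approaches significance — the expected
null outcome.

In Python the same analysis is three lines:

```python
from vowelspace import sample_cohort_truth, simulate_cohort, analyze_cohort
production, identification, truth = simulate_cohort(sample_cohort_truth(37, seed=3))
result = analyze_cohort(production, identification)   # .descriptives, .correlations
```

The estimator cores follow scikit-learn conventions
(`PsychometricLogistic().fit(steps, responses).width_`,
`MADScreen().fit(measures).transform(measures)`) and compose with
sklearn tooling.

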