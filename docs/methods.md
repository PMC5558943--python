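# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices, and the limitations of `trendlag`.

## Problem and model

The pipeline evaluates whether weekly normalized search-volume series
(values 0–100, with 0 doubling as "insufficient data") carry forecasting
information about monthly suicide counts. The central threat is spurious
correlation: two autocorrelated, seasonal, trending series correlate
substantially even when independent. The remedy is the classical
transfer-function approach:

1. model the explanatory series x with a seasonal ARIMA
   (p,d,q)(P,D,Q)₁₂ process;
2. filter **both** x and the dependent series y with that fitted model
   (prewhitening) — x becomes white-noise innovations, y becomes whatever
   structure it does not share with x;
3. cross-correlate the filtered pair at lags −3..+3.

Under the null of no cross-dependence the filtered pair is uncorrelated at
every lag, so the share of significant coefficients across many cells
estimates the test's Type-I-error rate; an excess over the nominal α is
the evidence threshold for genuine forecasting value.

### Lag sign convention

Pinned, because library conventions differ: lag k < 0 pairs x at month t
with y at month t+|k| — **x leads y**, the forecasting direction. Positive
lags mean the outcome preceded the searching; lag 0 is temporally
ambiguous. The synthetic transfer generator, the CCF, and the lead/lag
classifier all share this convention, and a shifted-copy test
(y_t = x_{t−2} + noise ⇒ peak at −2, never +2) guards it.

## Preparation rules

Weekly series are cropped of marginal missing runs, categorized
(complete / incomplete / peaks-only / no-data), and screened: span ≥ 36
calendar months, weekly missing fraction ≤ 0.10, longest interior missing
run ≤ 10 weeks. Missing fractions are computed **after** cropping — the
only reading consistent with spans reported post-crop. Remaining gaps are
linearly interpolated on the weekly grid; aggregation to months is an
exact day-count weighted average (each week contributes days to the one
or two months it straddles; proleptic Gregorian arithmetic, no 7/30
approximation). Margin months covered by fewer than 15 days are dropped
so no month is estimated from a sliver; 15 is a package choice — the
screening rules above are fixed by the study design, the margin-coverage
floor is not, and both the peaks-only operationalization (present
fraction ≤ 0.10 in runs ≤ 2 weeks) and the floor are configurable.

## Reliability

Repeated pulls of the same term differ; agreement is quantified by the
two-way consistency ICC from the row/column ANOVA decomposition:
ICC(C,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E), ICC(C,k) = (MS_R − MS_E)/MS_R,
which satisfy the Spearman–Brown relation exactly (e.g. a single-pull
reliability of .77 implies .971 for a 10-pull average). Confidence
intervals transform the F ratio MS_R/MS_E with (n−1, (n−1)(k−1)) degrees
of freedom; the F-based interval is a package choice, as no specific
interval method is canonical for this design. Negative estimates are
reported, not truncated. Pulls are aligned by inner join on dates before
forming the rectangular matrix; by default a time point missing in any
pull is dropped.

## Model selection

Identification by visual ACF/PACF inspection is replaced with an
exhaustive search over a small order grid (defaults p,q ≤ 4; d,D,P,Q ≤ 1;
s = 12; at most 6 ARMA parameters), estimated by exact maximum likelihood
(statsmodels SARIMAX, stationarity/invertibility enforced; an intercept
only for undifferenced models). A candidate is *adequate* when

1. every ARMA and outlier-regressor coefficient has two-sided p < .05
   (normal approximation; vacuously true for the white-noise model),
2. a one-sample t-test does not reject mean-zero residuals at .05,
3. the Ljung–Box–Pierce statistic at L = min(24, n/4) lags (degrees of
   freedom reduced by the ARMA parameter count) is not significant at .05.

Among adequate candidates the minimal-AICc model wins; ties go to fewer
parameters, then lower BIC, then lower AIC. Likelihoods of models with
different differencing orders live on different effective samples, so for
selection all information criteria are recomputed from the per-observation
log-likelihoods beyond the grid's largest differencing burn (d + D·s);
without this, seasonal differencing spuriously wins on white noise. If no
candidate is adequate, the minimal-AICc fit is returned flagged
`adequate=False`. The Ljung–Box horizon is a documented default, not an
assertion about any particular prior analysis.

### Outlier handling

On the selected model, every time point is scored with two statistics: the
innovational statistic λ₁ₜ = eₜ/σ̂ and the additive statistic
λ₂ₜ = Σⱼ πⱼ e_{t+j} / (σ̂ √Σπⱼ²), where π are the model's AR(∞) weights
(differencing included) — the imprint of a one-point additive shift on the
residual tail. The scale σ̂ is the robust √(π/2)·mean|e| estimate. The
largest |statistic| is flagged if it exceeds the Bonferroni critical value
over all 2n scanned statistics with a **t** reference at the scale
estimator's degrees of freedom, t₁₋α/(4n),ν=n. The t reference matters: the
maximum of hundreds of statistics standardized by a common estimated σ̂ is
very sensitive to scale error, and a normal critical value under-covers —
simulation places the family false-alarm rate near 13% for the normal
z₁₋α/(2n) value versus ~3–5% for the t version at α = .05. A flagged point
is classified by the larger statistic (AO on ties), entered as an ARIMAX
regressor — AO as a unit pulse, IO as the model's ψ-weight profile so a
single innovation shock propagates — and the scan repeats on the refit
until nothing exceeds the threshold (at most 10 rounds). Positions are
0-based. Injection-recovery simulations at 8σ give ≥ 90% correct
position-and-type for both AO and IO, with clean series flagged in ≲5% of
runs.

## Prewhitening and CCF

The explanatory series, minus the fitted contribution of its outlier
regressors (outliers are interventions on the search series, not on the
outcome, so no regressors are applied to y), and the dependent series are
both differenced per the model, demeaned, and whitened with the identical
frozen ARMA coefficients. Whitening uses the exact finite-sample Kalman
innovations of the stationary ARMA model rather than a zero-initialized
inverse-filter recursion: the innovations are variance-equalized from the
first observation and no start-up points are discarded, which at n = 84
months preserves roughly 15% of the usable sample and is what lifts the
detection power for a lag −2, r = .4 effect above 0.9.

Cross-correlations are plain Pearson correlations of the lag-shifted
overlap; each lag's significance band is z₁₋α/₂/√(n−|k|) with the per-lag
pair count (conservative and exact for the truncated overlap; the
1/√n-type band is itself a standard assumption, stated here explicitly).
Degenerate-variance lags yield NaN and are never significant.

## Evaluation grid and summaries

The reference design crosses 29 retained terms (12 USA pro-suicide, 7 USA
prevention, 5 German, 3 Austrian, 2 Swiss, with *depression*-type terms
classed separately) with five outcome strata — total, younger (<40),
older (40+), older men, older women — plus overall male/female strata for
the two overdose-method terms, at 7 lags: 29·5·7 + 2·2·7 = 1043
coefficients. The <40/40+ cut follows the overall mean age at suicide in
the source registers and is configurable.

Idealized patterns encode the a-priori forecasting hypothesis: magnitude
at lag 0 of .40 (total, older, older women, overdose-men) or .50
(younger, older men, overdose-women), shrinking by .10 per preceding lag,
positive for pro-suicide and depression terms, negative for prevention
terms, zero at positive lags. The per-cell concordance score is a package
invention (the original comparison was visual): each significant lag
contributes +1 when it sits at a non-positive lag with the expected sign
and −1 otherwise, averaged to [−1, 1], 0 when nothing is significant.

Effect-size bins on |r| are lower-inclusive at .10/.30/.50. Significance
is per-coefficient at α = .05 with **no** multiplicity correction by
default — the Type-I-error benchmark argument (observed % significant vs.
nominal 5%) requires uncorrected tests; a Bonferroni-style correction can
be applied by passing a smaller α.

## Synthetic data model

`GenSpec` draws a seasonal ARIMA path (polynomial stationarity and
invertibility are validated at construction), integrates d and D times,
and discards a 240-step warm-up. Weekly series are then shifted to a zero
minimum, scaled to a maximum of exactly 100, and rounded to integers —
the quantization the real exports apply, kept deliberately as a stress
test for downstream fitting. Missingness is injected to a target fraction
under a maximum-run constraint (feasibility checked at construction).
AO events add magnitude×σ to one observation; IO events add it to one
innovation before filtering. Pulls add independent Gaussian noise to the
shared latent path before each pull's own renormalization; noise sd 0.7
(on the latent scale of a unit-variance AR(1) with φ = .6) was calibrated
by simulation to a single-pull ICC near .75, the small-country regime,
and ICC decreases monotonically in the noise.

Outcome counts use a shared-filter construction: the outcome innovation at
month m is ρ·e_x[m+lag] + √(1−ρ²)·η_m, recolored with the same ARMA and
integration filter as x, then mapped to counts — by default an affine map
around `outcome_mean_level` (correlation-preserving, so the population
prewhitened CCF equals ρ at exactly the injected lag and 0 elsewhere), or
optionally a Poisson log-link, which attenuates the effect and produces
genuine integer counts. The affine "counts" are continuous and can in
principle go negative for strongly integrated paths; this is harmless for
correlation analysis and the Poisson option exists where count realism
matters.

What the generator does **not** emulate: the unknown sampling algorithm
behind pull-to-pull differences (noise is additive and homoscedastic; the
real asynchronicity reportedly varies over calendar time and is not
modelled), cross-term dependence within a region, media-event bursts
beyond single IO/AO events, and demographic structure in search behavior.
Passing tests therefore demonstrate the *statistical machinery* —
calibration, recovery, screening arithmetic — not the fidelity of any
particular real-world series.

## Calibration studies and problem sizes

The packaged calibration studies (also run by `scripts/acceptance.py` and
the test suite) use the modal generative structure
SARIMA(1,0,0)×(0,1,1)₁₂ with φ = .5, Θ = −.6 at n = 84 months:

- **Null calibration**: 500 independent pairs, true orders supplied to the
  fit; pooled share of significant coefficients across 3500 lags ≈ 5%
  (tolerance ±1.5 points).
- **Injection recovery**: 200 runs at ρ = .5, lag −2 — mean estimated r
  within ±.05 of .5 and peak at the injected lag in ≥ 90% of runs; 200
  runs at ρ = .4 — band-exceedance power ≥ .9.
- **Outlier machinery**: 50 seeds per scenario at 8σ, n = 150.

These sizes were chosen to keep each study's Monte-Carlo error well below
the tolerance it is checked against.

## Known limitations

- Coefficient p-values use the normal approximation to estimate/SE; no
  small-sample correction.
- AICc uses k counting all estimated parameters including the innovation
  variance; n is the full series length.
- The selection grid caps total ARMA parameters at 6; structures outside
  the grid (e.g. p = 5) are unreachable by design.
- Outlier taxonomy is IO/AO only — no level shifts or transient changes.
- The iterative outlier scan integrates one event per round and does not
  re-run full order selection afterwards; diagnostics are re-evaluated on
  the chosen specification only.
- Prewhitening assumes the dependent series shares the explanatory
  series' differencing orders; a y integrated of higher order than x
  would leave residual structure.
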