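# trendlag

Can normalized web-search volumes forecast national suicide rates? A naive
correlation between a search-volume series and a mortality series is almost
guaranteed to mislead: both carry trends, seasonality, and autocorrelation,
so wholly independent series routinely produce large spurious correlations.
`trendlag` implements the rigorous alternative — transfer-function
time-series analysis with prewhitening — as a tested, reusable pipeline for
infodemiology and suicide-surveillance research:

1. **Preparation** of weekly normalized search-volume series (0–100,
   Google-Trends-export style): margin cropping, availability
   categorization, inclusion screening (span ≥ 36 months, ≤ 10% missing
   weeks, no missing run > 10 weeks), linear interpolation, and exact
   calendar-weighted aggregation to months.
2. **Reliability** of repeated pulls of the same term via two-way
   consistency intraclass correlations, ICC(C,1)/ICC(C,k), with F-based
   confidence intervals, plus pull averaging.
3. **Box–Jenkins modelling** of the explanatory series: automated
   (S)ARIMA(p,d,q)(P,D,Q)₁₂ selection under three adequacy criteria
   (significant parameters, mean-zero residuals, Ljung–Box whiteness) with
   AICc/parsimony tie-breaks, and innovational/additive (IO/AO) outlier
   detection integrated through ARIMAX pulse regressors.
4. **Prewhitening and cross-correlation**: the explanatory model's filter,
   frozen, is applied to both series; cross-correlations at lags −3..+3
   get per-lag significance bands `z₁₋α/₂ / √(n−|k|)` and lead/lag
   interpretation (negative lag = searching precedes the outcome).
5. **Evaluation grid**: term × outcome-stratum cells (total, <40, 40+,
   older men, older women, plus male/female strata for overdose-method
   terms), idealized expected patterns (largest at lag 0, shrinking by .10
   per preceding month, signed by term class), effect-size bins, and the
   Type-I-error benchmark: under the null, ~5% of coefficients should be
   flagged at α = .05.

Because raw search-volume pulls and national mortality microdata are not
redistributable, a first-class synthetic generator emulates both: seasonal
ARIMA weekly series with 0–100 normalization, missingness, IO/AO events and
pull-to-pull noise, and monthly outcome counts with an optional cross-lagged
transfer effect whose population prewhitened cross-correlation is exactly
`target_ccf` at the injected lag.

## Worked example

Inject a moderate transfer effect (r = .5, search series leading the
outcome by 2 months) and recover it:

```python
import trendlag as tl

spec = tl.GenSpec(arima_orders=(1, 0, 0, 0, 1, 1), ar=(0.5,), seasonal_ma=(-0.6,))
x, y = tl.generate_pair(spec, tl.TransferSpec(target_ccf=0.5, lag=-2),
                        n_months=84, seed=11)

model = tl.select_model(x, tl.GridConfig(max_p=1, max_q=1, max_P=0))
pair = tl.prewhiten(x, y, model)
result = tl.ccf(pair, max_lag=3, alpha=0.05)
```

Output:

```
selected model: SARIMA(1,0,0)x(0,1,1)_12 adequate: True
lag -3: r = +0.085  band = ±0.236
lag -2: r = +0.522  band = ±0.234  significant
lag -1: r = +0.014  band = ±0.233
lag +0: r = -0.091  band = ±0.231
lag +1: r = -0.094  band = ±0.233
lag +2: r = -0.077  band = ±0.234
lag +3: r = -0.091  band = ±0.236
peak lag: -2
```

The grid search recovers the generating seasonal structure, the prewhitened
cross-correlation peaks at exactly the injected lag with roughly the
injected magnitude, and every other lag stays inside its significance band.
A significant coefficient at a *negative* lag is the forecasting direction:
search activity at month *t* is associated with the outcome |lag| months
later.

A thin CLI covers the same stages (`trendlag simulate`, `reliability`,
`fit`, `ccf`, `run`); see `trendlag --help`.

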