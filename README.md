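# phenocurve

Growth-curve phenology analysis for UAV-monitored rice trials: reduce
per-line time series of canopy height (CH) and chlorophyll index green
(CIg) to interpretable curve parameters, predict manually measured traits
from those parameters with linear models, and calibrate predictions across
cultivation conditions using parental cultivars as anchors.

Intended for crop phenomics researchers running multi-condition field
trials (different transplanting protocols, different years) who want
interpretable, per-line phenology features rather than black-box
predictors.

## The models

Canopy height over days after transplanting `x` follows a modified
three-parameter logistic with a quadratic late decline,

    y(x) = K / (1 + exp(r1 (d0 − x)))                 x ≤ d1
    y(x) = K / (1 + exp(r1 (d0 − x))) − a (x − d1)²   x > d1

(`K` maximum height, `r1` growth rate, `d0` day of fastest growth, `d1`
day the maximum is reached, `a` late decline rate).  CIg follows a double
logistic,

    y(x) = ymax [ 1/(1 + exp(r2 (d2 − x))) − 1/(1 + exp(r3 (d3 − x))) ]

(rise around `d2` at rate `r2`, fall around `d3` at rate `r3`, scale
`ymax`).  Both are fitted per line by bounded nonlinear least squares;
`ymax` is fixed at the observed series maximum and the remaining double
logistic parameters start from the conventional (0.05, 0.05, 40, 100).

The ten fitted parameters feed six linear trait-prediction models (CH,
CIg or Hybrid predictor pools; full or VIF-selected, threshold 5), which
are evaluated by four schemes — fitness, repeated 10-fold CV, cross-
protocol (type-1) and cross-year (type-2) robustness — and corrected by
an affine calibration learned from the parental cultivars' predicted vs
observed values.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from phenocurve import (CHParams, ObservationSeries, evaluate_ch_model,
                        fit_ch_model)

days = np.arange(7, 141, 7.0)
true = CHParams(K=100, r1=0.11, d0=42, d1=76, a=0.008)
rng = np.random.default_rng(0)
y = evaluate_ch_model(days, true) + rng.normal(0, 1, days.size)

fit = fit_ch_model(ObservationSeries("L001", "CH", days, y))
print(f"K={fit.params.K:.1f} cm  d0={fit.params.d0:.1f} d  "
      f"d1={fit.params.d1:.1f} d  R2={fit.r_squared:.4f}")
```

prints

```
K=98.9 cm  d0=41.6 d  d1=74.7 d  R2=0.9997
```

i.e. the fitted curve explains 99.9% of the series variance, the maximum
height and the day of fastest growth are recovered almost exactly, and the
peak day `d1` lands within ~3 days — its intrinsic precision at weekly
sampling and 1 cm noise (see `docs/methods.md`).

A whole synthetic campaign, end to end:

```
phenocurve run --n-lines 100 --seed 1 --out campaign_out
```

writes `series.csv`, `traits.csv`, `params.csv`, `eval.csv`,
`calibration.csv` and a text report of per-trait, per-model R²/RMSE/cor
under all four schemes.  The other subcommands (`simulate`, `extract`,
`fit-curves`, `select`, `calibrate`) expose the individual stages.

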