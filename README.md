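# pulmoref

Clinical-style reference values for rat lung function.

In human pulmonology a measurement is rarely reported as an absolute
number: it is placed in a reference distribution conditioned on who the
patient is, and interpreted as a z-score or percentile.  `pulmoref` brings
the same framework to preclinical respiratory research in the two most
common laboratory rat strains.  It provides prediction equations,
z-scores, percentiles and normal ranges for four outcomes measured in
anesthetized, ventilated Sprague Dawley and Wistar rats:

| outcome | symbol | units | scale |
|---|---|---|---|
| airway resistance | Raw | cmH₂O·s/l | log |
| tissue damping | G | cmH₂O/l | log |
| tissue elastance | H | cmH₂O/l | log |
| end-expiratory lung volume | EELV | ml | identity |

## The model

Each outcome carries a Gaussian location-scale (GAMLSS-style) model with
two linear predictors: one for the mean µ and one for the log standard
deviation σ,

```
µ = a₀ + a₁·√mass + a₂·I(strain = Wistar) + a₃·I(sex = male) + PEEP_effect
σ = exp(b₀ + b₁·mass + b₂·I(strain = Wistar) + b₃·I(sex = male) + PEEP_effect)
```

with body mass in grams, PEEP ∈ {0, 1, 2, 3, 4, 6} cmH₂O as a categorical
factor (level 0 is the reference), and µ on the natural-log scale for
Raw/G/H.  A measurement y is standardized as z = (T(y) − µ)/σ with T = log
or identity; |z| ≤ 1.645 bounds the central 90% of healthy animals.

Beyond the bundled published coefficients, the package contains the whole
pipeline behind such equations:

- `fit` — exact maximum-likelihood fitting of the location-scale model
  (identity/log µ link, log σ link), with Cox–Snell R², GAIC and residual
  diagnostics;
- `cohort` — a seeded synthetic-cohort generator emulating the study
  population (four strain×sex groups, right-skewed masses, outcomes drawn
  from the reference models);
- `crossval` — Monte Carlo cross-validation (70/30 splits by animal) with
  pooled z statistics, 90%/95% coverage, RMSE and MAE;
- `impedance` — the constant-phase model of respiratory input impedance,
  Zrs = Raw + iωIaw + (G − iH)/ω^α with α = (2/π)·atan(H/G), including
  synthesis, equipment subtraction, ensemble averaging and relative
  least-squares fitting — the upstream computation that produces Raw, G
  and H;
- `plethysmography` — end-expiratory lung volume from occluded-breathing
  box/tracheal pressure traces via the Boyle–Mariotte relation
  EELV = −s·β·(V_box − V_rat) − V_ds — the upstream computation that
  produces EELV.

## Worked example

```python
import pulmoref as pr

models = pr.default_models()
raw_model = models[pr.Outcome.RAW]
cov = pr.CovariateSet(mass_g=250, strain="sprague_dawley",
                      sex="female", peep_cmH2O=2)

result = raw_model.z_score(cov, observed=60.0)
lo, hi = raw_model.normal_range(cov, central_mass=0.90)
```

prints (see `examples/01_zscores_and_normal_ranges.py`):

```
predicted median Raw : 47.1 cmH2O.s/l
normal range (90%)   : 31.2 - 71.0 cmH2O.s/l
observed 60.0        : z = +0.97, percentile 83.4
classification       : within_range
```

The animal's measured Raw of 60 cmH₂O·s/l sits about one reference
standard deviation above the predicted median on the log scale — elevated
but within the central 90% of healthy animals of her size, sex, strain
and PEEP.  The `examples/` directory holds one short script per
capability (prediction, simulate-and-refit, cross-validation, impedance
fitting, EELV); each prints the numbers it computes and what they mean.

A thin command line mirrors the library for shell use:

```
pulmoref simulate -o cohort.csv --seed 1
pulmoref fit cohort.csv --outcome raw -o fit.json
pulmoref crossval cohort.csv --outcome raw -o cv.json --seed 1
pulmoref predict cohort.csv -o zscores.csv
pulmoref fit-impedance spectrum.csv -o params.json
pulmoref eelv trace.csv --mass 300 --cannula 2.5 -o eelv.json
```

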