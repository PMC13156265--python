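# Methods

## The reference model

Each outcome (Raw, G, H, EELV) is modelled as Gaussian on a transformed
scale: T(y) ~ Normal(µ, σ) with T the natural logarithm for Raw, G and H
(which are right-skewed and heteroscedastic in the original units) and
the identity for EELV.  Both distribution parameters are linear in the
covariates:

- µ = a₀ + a₁·√mass + a₂·I_Wistar + a₃·I_male + PEEP_effect
- log σ = b₀ + b₁·mass + b₂·I_Wistar + b₃·I_male + PEEP_effect

Notes on the coding, which the fitter and the bundled coefficients share:

- body mass enters µ as √mass but σ as untransformed mass, both in grams;
- strain and sex are indicators (1 for Wistar, 1 for male);
- PEEP ∈ {0, 1, 2, 3, 4, 6} cmH₂O is categorical with level 0 as the
  reference (effect exactly 0); there is no interpolation between levels;
- terms excluded from a final model (stored as absent) contribute exactly
  zero, and the bundled coefficient document stores every published value
  at its full printed precision of five decimals.

z-scores are computed on the transformed scale, z = (T(y) − µ)/σ.  For
log outcomes this makes the reference distribution log-normal in original
units, so the predicted "median" exp(µ) is the 50th percentile, not the
mean.  The natural logarithm is assumed throughout, consistent with a
Gaussian family under a log link.  Classification against the normal
range defaults to |z| ≤ 1.645 (central 90%); the bound and the width of
`normal_range` are configurable.

Applicability: the equations were built from animals of roughly
164–376 g (females) and 156–750 g (males, upper end Sprague Dawley only).
Outside the per-group mass range the package still predicts but emits an
`ApplicabilityWarning` — extrapolation, not failure, mirroring how human
reference equations are used in practice.

### Effect sizes

Strain and sex effects are summarized two ways.  Percent change of the
median: 100·(e^a − 1) for log outcomes; for EELV (identity link) the
coefficient is divided by the reference prediction averaged over PEEP
levels, a choice made here because a multiplicative effect is undefined
on the identity scale.  A Cohen-style d is |a|/σ̄, where σ̄ is the σ
submodel evaluated at reference covariates (Sprague Dawley female, the
group's median mass of 258 g) averaged over the six PEEP levels.  The
standardizer is a genuine modelling choice — σ varies with covariates, so
no single "the" standard deviation exists; this one is documented and
overridable via the `mass_g` argument.  Class thresholds: 0.2 small,
0.5 medium, 0.8 large, 1.2 very large.

## Estimation

The location-scale model is fitted by maximizing the exact Gaussian
log-likelihood jointly in (a, b).  The algorithm alternates two steps,
each exact or second-order:

1. µ step: given σ, weighted least squares with weights 1/σᵢ² (the exact
   conditional maximizer);
2. σ step: damped Newton updates in b using the analytic gradient
   Xᵀ(u − 1) and Hessian −2XᵀUX, where uᵢ = (rᵢ/σᵢ)².

Once the joint gradient is small, full joint Newton steps with the
analytic observed-information matrix polish the optimum; plain
alternation converges only linearly when the two submodels are strongly
coupled.  Design columns are internally scaled to unit maximum (mass in
grams would otherwise dominate the σ-gradient and the information
matrix); coefficients and standard errors are transformed back.

Starting values: OLS for a, log of the maximum-likelihood residual SD
(divisor n) for b₀, zeros elsewhere.  Convergence requires both a
relative log-likelihood change below 1e-10 and a gradient max-norm below
1e-6 scaled by |ℓ| (the gradient sums over observations and grows with
n).  An exact likelihood plateau with the criterion unmet is reported as
`converged = False` — never silently as success.  Standard errors come
from the inverse observed information at the optimum.  With an
intercept-only σ submodel the fit reduces exactly to OLS plus the MLE
residual SD, which the tests verify against a closed-form oracle.

Observations are treated as independent across animals and PEEP levels —
deliberately no random animal effect, matching the final published model
(subject-level effects degraded predictive coverage).

Fit summaries: Cox–Snell R² = 1 − exp((2/n)(ℓ₀ − ℓ₁)) against an
intercepts-only null model (both submodels reduced to intercepts — the
null's σ must be free or the statistic conflates mean and variance
explanation); GAIC = −2ℓ + k·(number of parameters), k = 2 giving AIC.
Residual diagnostics (mean, SD, skewness, excess kurtosis, normal Q–Q of
standardized residuals) use residuals on the fitting scale — log for
Raw/G/H, original units for EELV — which is the convention under which
the published residual SDs (e.g. ≈0.27 for Raw) are interpretable.

Model selection is intentionally out of scope: `DesignSpec` is explicit,
and `published_design()` returns each outcome's final published term set.
The original selection blended information criteria, residual diagnostics
and cross-validation judgment and is not a reproducible algorithm.

## Synthetic cohorts

The generator emulates the study population so that every downstream
stage is testable without any data download.

- Group sizes and mass summaries default to the printed cohort: 52 male /
  46 female Sprague Dawley, 53 male / 31 female Wistar (the figure
  caption's 52 Wistar males is a discrepancy in the source; the animal
  count section's 53 is used), with medians 317/258/310/260 g and the
  printed min–max ranges.
- Masses are drawn from a log-normal truncated to [min, max] with
  location log(median) and scale (log max − log min)/(2·1.96), i.e. the
  central 95% of the untruncated law roughly spans the printed range.
  Only median/min/max are published; any right-skewed, range-respecting,
  median-preserving shape is admissible, and this one is the simplest.
  Verified properties: all masses in range, positive skew, sample median
  within ±10 g of the target at large n.
- Outcomes are drawn as T(y) ~ Normal(µ, σ) from the reference models and
  back-transformed; exponentiation keeps Raw/G/H strictly positive.
  Noise is independent across PEEP levels within an animal (again: the
  final model has no random effect).  EELV at the highest PEEP can be set
  missing with configurable probability, emulating animals without
  breathing efforts against the occlusion.
- A single integer seed determines the whole cohort (NumPy PCG64).

What passing tests on such cohorts do **not** show: robustness to
within-animal correlation, model misspecification, measurement drift or
between-laboratory effects — none of which the generator produces.  The
cross-validation coverage results below are statements about a correctly
specified model.

## Monte Carlo cross-validation

Default configuration: 50 iterations, 70/30 train/test, split **by
animal** so all six PEEP rows of an animal stay on one side — the
conservative choice, preventing animal-level information leaking across
the split (the source does not state its split unit; row-level splitting
is available as an option).  Per iteration the model is refitted on the
training animals; held-out animals get z-scores on the modelling scale
and predictions in original units (back-transformed for log outcomes).

Aggregation: z mean/SD/range and the 90%/95% coverages are computed on
the z-scores pooled over all iterations (matching a single printed
summary per outcome), while RMSE and MAE are computed per iteration and
summarized as mean/SD/range over iterations.  Iterations that fail to
converge are excluded and counted, never silently averaged.

On self-simulated study-sized cohorts (182 animals) the pooled z SD is
systematically slightly above 1 (~1.02) and coverage slightly below
nominal (~89.5% / ~94.6%): with ~760 training rows and 16 parameters,
estimation error widens held-out z-scores.  The calibration checks in the
acceptance suite therefore average three replicate cohorts, targeting
this systematic value rather than the sampling noise of one cohort draw;
the acceptance script does the same.

## Constant-phase impedance model

Zrs(f) = Raw + iωIaw + (G − iH)/ω^α, ω = 2πf, α = (2/π)·atan(H/G)
recomputed from G and H, never stored.  The default frequency grid takes
multiples of 0.25 Hz in [0.5, 20.75] and keeps a multiple whenever it
neither divides nor is divided by one already kept (a greedy scan) —
yielding exactly 23 pairwise non-harmonic components, the grid size and
span used with the pseudorandom forcing signal.  The exact study
components are not published; any non-harmonic grid works, and the fit
API accepts arbitrary grids.

Fitting minimizes Σ|Z_meas − Z_model|²/|Z_meas|² — squared relative
modulus error, implemented as a bounded trust-region least-squares
problem on the residual vector (ΔRe/|Z|, ΔIm/|Z|).  "Relative
difference" admits several readings; the modulus-relative form treats
real and imaginary parts symmetrically and equalizes frequencies whose
impedance spans orders of magnitude.  G and H are log-parameterized
(strict positivity); Raw and Iaw are bounded at zero.  Initialization
from the asymptotes: Raw from the high-frequency real part, G and H from
the lowest-frequency point with α seeded at 0.8.  Noiseless synthetic
spectra are recovered to better than 1e-6 relative error, including from
initializations an order of magnitude off.

## Plethysmographic EELV

EELV = −s·β·(V_box − V_rat) − V_ds, with s the slope of box on tracheal
pressure during occluded inspiratory efforts, β = (Patm − PH₂O)/Patm,
V_rat = mass/1.025 g·cm⁻³ and V_ds the cannula dead space (0.53 ml for
the 2.0 mm, 0.65 ml for the 2.5 mm cannula).  Defaults: 1910 ml chamber;
Patm 760 mmHg and PH₂O 47 mmHg at 37 °C — standard-physiology values,
configurable, and only their ratio matters.

Effort detection baseline-corrects the tracheal signal using the trace
median (robust, since efforts occupy a minority of samples and the
analysis cannot know where the pre-occlusion segment ends); samples with
deflection below −20% of the maximal deflection count as inspiratory
effort, rejecting the much smaller cardiogenic oscillations.  The sign
convention is p_trach < baseline during occluded inspiration.  Both the
threshold fraction and an absolute threshold are configurable.  The
Pbox–Ptrach regression must reach r² ≥ 0.95 (configurable) before a
volume is reported; failed linearity or a negative volume yields an
invalid result with NaN volume, mirroring unusable occlusions.

The simulator inverts the relation — s = −(EELV + V_ds)/(β(V_box −
V_rat)) — and builds a 12 s, 256 Hz trace with sinusoid-like efforts,
optional ~5 Hz cardiogenic ripple and sensor noise.  Noiseless traces
round-trip to numerical accuracy over EELV ∈ {5, 10, 15} ml, masses
{200, 300, 500} g and both cannulas; with realistic noise the bias stays
under 2% (noise on the regressor attenuates the slope only ~0.1% at the
default amplitudes).

## Problem sizes and determinism

Everything is seeded; a config plus seed reproduces a cohort, a CV run or
a trace bit-for-bit.  The test suite and the acceptance script use
study-scale problems throughout — 2000-animal cohorts for coefficient
recovery (ten seeds averaged for the µ terms, whose per-seed estimator SD
of ~0.005 would otherwise dominate the comparison), 182-animal cohorts
for cross-validation (three replicates averaged), 200 replicate spectra
for the impedance noise study — chosen so each check measures its
systematic quantity with comfortable Monte Carlo margin.

## Known limitations

- The coefficients are specific to the measurement conditions
  (anesthetized, ventilated, tracheostomized animals; forced oscillations;
  body plethysmography) and to Sprague Dawley and Wistar rats within the
  stated mass ranges.
- The fitter covers the Gaussian location-scale family only — no splines,
  no other distributions, no covariate-selection search.
- Upstream signal processing (computing Zrs from raw wave-tube pressure
  recordings, FFT windowing) is out of scope; the impedance module starts
  from spectra.
- The synthetic generator's mass-distribution shape and the simulator's
  effort/noise shapes are plausible stand-ins, not estimates from raw
  data.
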