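"""Published reference equations for rat lung function and their use.

Each outcome (Raw, G, H, EELV) carries a Gaussian location-scale reference
model with two linear submodels,

    mu    = a0 + a1*sqrt(mass_g) + a2*I_Wistar + a3*I_male + PEEP_effect
    sigma = exp(b0 + b1*mass_g + b2*I_Wistar + b3*I_male + PEEP_effect)

where mu lives on the natural-log scale for Raw/G/H and on the original
scale for EELV, and sigma is always strictly positive through its log link.
PEEP enters both submodels as a per-level offset with level 0 cmH2O as the
reference (effect exactly 0); terms excluded from a final model contribute
exactly 0.  From mu and sigma the module derives predicted medians,
z-scores, percentiles, normal ranges and standardized effect sizes for
arbitrary covariate combinations.

The bundled coefficient document reproduces the published models at their
full printed precision (five decimals).
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import (
    ApplicabilityWarning,
    InvalidCovariateError,
    InvalidObservationError,
    SchemaError,
)
from .outcomes import (
    PEEP_LEVELS,
    CovariateSet,
    Outcome,
    OutcomeSpec,
    Sex,
    Strain,
    outcome_spec,
)

#: Body-mass range (grams) spanned by the study cohort, per strain and sex.
#: Predictions outside these ranges are extrapolations and raise
#: :class:`~pulmoref.exceptions.ApplicabilityWarning`.
DEFAULT_APPLICABILITY = {
    (Strain.SPRAGUE_DAWLEY, Sex.MALE): (170.0, 750.0),
    (Strain.SPRAGUE_DAWLEY, Sex.FEMALE): (164.0, 376.0),
    (Strain.WISTAR, Sex.MALE): (156.0, 530.0),
    (Strain.WISTAR, Sex.FEMALE): (162.0, 366.0),
}

#: Cohort median body mass (grams) per strain and sex, used as the default
#: evaluation point for standardized effect sizes.
COHORT_MEDIAN_MASS = {
    (Strain.SPRAGUE_DAWLEY, Sex.MALE): 317.0,
    (Strain.SPRAGUE_DAWLEY, Sex.FEMALE): 258.0,
    (Strain.WISTAR, Sex.MALE): 310.0,
    (Strain.WISTAR, Sex.FEMALE): 260.0,
}

_Z90 = 1.645  # default |z| bound: central 90% of the reference distribution


@dataclass(frozen=True)
class LocationScaleCoefficients:
    """Coefficients of one outcome's location-scale model.

    ``None`` marks a term excluded from the final model; it contributes
    exactly zero.  ``sigma_peep_effects`` may be absent as a whole (the H
    model has no PEEP term in its sigma submodel).
    """

    a0: float
    a1: float  # sqrt(mass [g])
    a2: float  # I_Wistar
    a3: float  # I_male
    mu_peep_effects: Mapping[int, float]
    b0: float
    b1: float | None = None  # mass [g]
    b2: float | None = None  # I_Wistar
    b3: float | None = None  # I_male
    sigma_peep_effects: Mapping[int, float] | None = None

    def __post_init__(self):
        mu_peep = dict(self.mu_peep_effects)
        if mu_peep.get(0, 0.0) != 0.0:
            raise SchemaError("reference-level PEEP effect (0 cmH2O) must be exactly 0")
        mu_peep.setdefault(0, 0.0)
        object.__setattr__(self, "mu_peep_effects", mu_peep)
        if self.sigma_peep_effects is not None:
            sig_peep = dict(self.sigma_peep_effects)
            if sig_peep.get(0, 0.0) != 0.0:
                raise SchemaError("reference-level PEEP effect (0 cmH2O) must be exactly 0")
            sig_peep.setdefault(0, 0.0)
            object.__setattr__(self, "sigma_peep_effects", sig_peep)


@dataclass(frozen=True)
class ZScoreResult:
    """A single observation placed in its reference distribution."""

    mu: float
    sigma: float
    predicted_median: float
    z: float
    percentile: float
    classification: str  # below_range | within_range | above_range


#: Cohen-style magnitude classes for standardized effect sizes.
D_CLASS_THRESHOLDS = ((1.2, "very_large"), (0.8, "large"), (0.5, "medium"), (0.2, "small"))


def classify_d(d: float) -> str:
    for threshold, label in D_CLASS_THRESHOLDS:
        if abs(d) >= threshold:
            return label
    return "below_small"


@dataclass(frozen=True)
class EffectSizeReport:
    covariate: str  # "strain" | "sex"
    percent_change_mu: float
    percent_change_sigma: float | None
    d_value: float | None
    d_class: str


@dataclass(frozen=True)
class ReferenceModel:
    """One outcome's reference equation plus its applicability envelope."""

    spec: OutcomeSpec
    coefficients: LocationScaleCoefficients
    applicability: Mapping[tuple[Strain, Sex], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_APPLICABILITY)
    )

    # -- core predictions ------------------------------------------------
    def _check_applicability(self, cov: CovariateSet) -> None:
        lo, hi = self.applicability[(cov.strain, cov.sex)]
        if not (lo <= cov.mass_g <= hi):
            warnings.warn(
                f"body mass {cov.mass_g:g} g outside the {cov.strain.value} "
                f"{cov.sex.value} reference range [{lo:g}, {hi:g}] g; "
                "prediction is an extrapolation",
                ApplicabilityWarning,
                stacklevel=3,
            )

    def mu(self, cov: CovariateSet) -> float:
        """Linear predictor of the mean on the modelling scale."""
        self._check_applicability(cov)
        c = self.coefficients
        if cov.peep_cmH2O not in c.mu_peep_effects:
            raise InvalidCovariateError(f"no PEEP effect for level {cov.peep_cmH2O}")
        return (
            c.a0
            + c.a1 * math.sqrt(cov.mass_g)
            + c.a2 * cov.i_wistar
            + c.a3 * cov.i_male
            + c.mu_peep_effects[cov.peep_cmH2O]
        )

    def sigma(self, cov: CovariateSet) -> float:
        """Standard deviation on the modelling scale (always positive).

        Note the sigma submodel uses untransformed mass, unlike mu which
        uses sqrt(mass).
        """
        c = self.coefficients
        lin = c.b0
        if c.b1 is not None:
            lin += c.b1 * cov.mass_g
        if c.b2 is not None:
            lin += c.b2 * cov.i_wistar
        if c.b3 is not None:
            lin += c.b3 * cov.i_male
        if c.sigma_peep_effects is not None:
            if cov.peep_cmH2O not in c.sigma_peep_effects:
                raise InvalidCovariateError(f"no PEEP effect for level {cov.peep_cmH2O}")
            lin += c.sigma_peep_effects[cov.peep_cmH2O]
        return math.exp(lin)

    def predicted_median(self, cov: CovariateSet) -> float:
        """Predicted 50th-percentile value in original units."""
        return float(self.spec.back_transform(self.mu(cov)))

    def z_score(
        self, cov: CovariateSet, observed: float, z_bound: float = _Z90
    ) -> ZScoreResult:
        """Place an observed value (original units) in the reference
        distribution.

        z is computed on the modelling scale: (T(observed) - mu)/sigma with
        T = natural log for Raw/G/H and identity for EELV.
        """
        if self.spec.mu_transform == "log" and not observed > 0:
            raise InvalidObservationError(
                f"{self.spec.name.value} is modelled on the log scale; "
                f"observed value must be positive, got {observed!r}"
            )
        mu = self.mu(cov)
        sigma = self.sigma(cov)
        z = (float(self.spec.transform(observed)) - mu) / sigma
        percentile = 100.0 * stats.norm.cdf(z)
        if z < -z_bound:
            label = "below_range"
        elif z > z_bound:
            label = "above_range"
        else:
            label = "within_range"
        return ZScoreResult(
            mu=mu,
            sigma=sigma,
            predicted_median=float(self.spec.back_transform(mu)),
            z=z,
            percentile=percentile,
            classification=label,
        )

    def normal_range(
        self, cov: CovariateSet, central_mass: float = 0.90
    ) -> tuple[float, float]:
        """Symmetric reference interval in original units.

        Limits sit at mu +/- z* sigma on the modelling scale with
        z* = Phi^-1((1 + central_mass)/2), then are back-transformed.
        """
        if not 0 < central_mass < 1:
            raise InvalidCovariateError(
                f"central_mass must lie in (0, 1), got {central_mass!r}"
            )
        mu = self.mu(cov)
        sigma = self.sigma(cov)
        z_star = stats.norm.ppf((1 + central_mass) / 2)
        lo = float(self.spec.back_transform(mu - z_star * sigma))
        hi = float(self.spec.back_transform(mu + z_star * sigma))
        return lo, hi

    # -- effect sizes ----------------------------------------------------
    def effect_sizes(self, covariate: str, mass_g: float | None = None) -> EffectSizeReport:
        """Percent changes and a Cohen-style d for strain or sex.

        Percent change in the median comes from the mu coefficient
        (100*(exp(a)-1) for log outcomes; for EELV relative to the reference
        prediction averaged over PEEP).  The standardizer for d is sigma at
        the reference covariates (Sprague Dawley female, cohort median mass
        unless ``mass_g`` is given), averaged over the six PEEP levels.
        """
        if covariate not in ("strain", "sex"):
            raise InvalidCovariateError(f"covariate must be 'strain' or 'sex', got {covariate!r}")
        c = self.coefficients
        a_coef = c.a2 if covariate == "strain" else c.a3
        b_coef = c.b2 if covariate == "strain" else c.b3
        if mass_g is None:
            mass_g = COHORT_MEDIAN_MASS[(Strain.SPRAGUE_DAWLEY, Sex.FEMALE)]
        ref_covs = [
            CovariateSet(mass_g=mass_g, strain=Strain.SPRAGUE_DAWLEY, sex=Sex.FEMALE, peep_cmH2O=p)
            for p in PEEP_LEVELS
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ApplicabilityWarning)
            sigma_bar = float(np.mean([self.sigma(cv) for cv in ref_covs]))
            if self.spec.mu_transform == "log":
                pct_mu = 100.0 * (math.exp(a_coef) - 1.0)
            else:
                mu_bar = float(np.mean([self.mu(cv) for cv in ref_covs]))
                pct_mu = 100.0 * a_coef / mu_bar
        pct_sigma = None if b_coef is None else 100.0 * (math.exp(b_coef) - 1.0)
        d = abs(a_coef) / sigma_bar
        return EffectSizeReport(
            covariate=covariate,
            percent_change_mu=pct_mu,
            percent_change_sigma=pct_sigma,
            d_value=d,
            d_class=classify_d(d),
        )


# -- functional aliases matching the published formula names --------------
def compute_mu(model: ReferenceModel, cov: CovariateSet) -> float:
    return model.mu(cov)


def compute_sigma(model: ReferenceModel, cov: CovariateSet) -> float:
    return model.sigma(cov)


def predicted_median(model: ReferenceModel, cov: CovariateSet) -> float:
    return model.predicted_median(cov)


def z_score(model: ReferenceModel, cov: CovariateSet, observed: float) -> ZScoreResult:
    return model.z_score(cov, observed)


def normal_range(model, cov, central_mass: float = 0.90):
    return model.normal_range(cov, central_mass)


def effect_sizes(model: ReferenceModel, covariate: str) -> EffectSizeReport:
    return model.effect_sizes(covariate)


# -- coefficient document I/O ---------------------------------------------
_MU_KEYS = {"intercept", "sqrt_mass", "strain_wistar", "sex_male", "peep"}
_SIGMA_KEYS = {"intercept", "mass", "strain_wistar", "sex_male", "peep"}


def _parse_peep_map(obj, where: str) -> dict[int, float]:
    try:
        parsed = {int(k): float(v) for k, v in obj.items()}
    except (AttributeError, TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: PEEP effects must map level -> number", [where]) from exc
    unknown = sorted(set(parsed) - set(PEEP_LEVELS))
    if unknown:
        raise SchemaError(f"{where}: unknown PEEP levels {unknown}", [where])
    return parsed


def _model_from_document(name: str, doc: Mapping) -> ReferenceModel:
    try:
        out = Outcome(name)
    except ValueError as exc:
        raise SchemaError(f"unknown outcome {name!r}", [name]) from exc
    spec = outcome_spec(out)
    missing = [k for k in ("mu", "sigma") if k not in doc]
    if missing:
        raise SchemaError(f"{name}: missing blocks {missing}", missing)
    mu, sigma = doc["mu"], doc["sigma"]
    bad = sorted(set(mu) - _MU_KEYS) + sorted(set(sigma) - _SIGMA_KEYS)
    if bad:
        raise SchemaError(f"{name}: unknown coefficient keys {bad}", bad)
    missing_mu = sorted(_MU_KEYS - set(mu))
    if missing_mu:
        raise SchemaError(f"{name}: mu submodel missing keys {missing_mu}", missing_mu)
    if "intercept" not in sigma:
        raise SchemaError(f"{name}: sigma submodel missing intercept", ["intercept"])
    try:
        coeffs = LocationScaleCoefficients(
            a0=float(mu["intercept"]),
            a1=float(mu["sqrt_mass"]),
            a2=float(mu["strain_wistar"]),
            a3=float(mu["sex_male"]),
            mu_peep_effects=_parse_peep_map(mu["peep"], f"{name}.mu"),
            b0=float(sigma["intercept"]),
            b1=float(sigma["mass"]) if "mass" in sigma else None,
            b2=float(sigma["strain_wistar"]) if "strain_wistar" in sigma else None,
            b3=float(sigma["sex_male"]) if "sex_male" in sigma else None,
            sigma_peep_effects=(
                _parse_peep_map(sigma["peep"], f"{name}.sigma") if "peep" in sigma else None
            ),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{name}: non-numeric coefficient ({exc})", [name]) from exc
    return ReferenceModel(spec=spec, coefficients=coeffs)


def load_reference_coefficients(source=None) -> dict[Outcome, ReferenceModel]:
    """Load reference models from a coefficient document.

    ``source`` may be a path to a JSON document, an already-parsed mapping,
    or ``None`` for the bundled document, which reproduces the published
    coefficient table exactly.
    """
    if source is None:
        text = resources.files("pulmoref.data").joinpath(
            "reference_coefficients.json"
        ).read_text()
        raw = json.loads(text)
    elif isinstance(source, Mapping):
        raw = source
    else:
        with open(source) as fh:
            raw = json.load(fh)
    if not isinstance(raw, Mapping):
        raise SchemaError("coefficient document must be a JSON object")
    models = {}
    for name, doc in raw.items():
        model = _model_from_document(name, doc)
        models[model.spec.name] = model
    return models


def default_models() -> dict[Outcome, ReferenceModel]:
    """The four bundled reference models keyed by outcome."""
    return load_reference_coefficients(None)


# -- vectorized evaluation over cohort tables ------------------------------
def mu_sigma_arrays(model: ReferenceModel, frame) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate mu and sigma for every row of a cohort-style frame.

    ``frame`` needs columns ``mass_g``, ``strain``, ``sex``, ``peep_cmH2O``.
    No applicability warning is emitted here; batch callers are expected to
    validate covariates up front.
    """
    c = model.coefficients
    mass = np.asarray(frame["mass_g"], float)
    wistar = (np.asarray(frame["strain"]).astype(str) == Strain.WISTAR.value).astype(float)
    male = (np.asarray(frame["sex"]).astype(str) == Sex.MALE.value).astype(float)
    peep = np.asarray(frame["peep_cmH2O"], int)
    unknown = sorted(set(peep) - set(PEEP_LEVELS))
    if unknown:
        raise InvalidCovariateError(f"unknown PEEP levels {unknown}")
    mu = (
        c.a0
        + c.a1 * np.sqrt(mass)
        + c.a2 * wistar
        + c.a3 * male
        + np.array([c.mu_peep_effects[p] for p in peep])
    )
    lin = np.full(len(mass), c.b0)
    if c.b1 is not None:
        lin += c.b1 * mass
    if c.b2 is not None:
        lin += c.b2 * wistar
    if c.b3 is not None:
        lin += c.b3 * male
    if c.sigma_peep_effects is not None:
        lin += np.array([c.sigma_peep_effects[p] for p in peep])
    return mu, np.exp(lin)


def predict_frame(model: ReferenceModel, frame, observed=None):
    """Per-row predictions (and z-scores when observations are supplied).

    Returns a :class:`pandas.DataFrame` with columns ``mu``, ``sigma`` and
    ``predicted_median``; with ``observed`` (array of values in original
    units, NaN = missing) it also fills ``z``, ``percentile`` and
    ``classification``.
    """
    import pandas as pd

    mu, sigma = mu_sigma_arrays(model, frame)
    out = pd.DataFrame(
        {
            "mu": mu,
            "sigma": sigma,
            "predicted_median": np.asarray(model.spec.back_transform(mu), float),
        },
        index=getattr(frame, "index", None),
    )
    if observed is not None:
        obs = np.asarray(observed, float)
        if model.spec.mu_transform == "log" and np.any(obs[np.isfinite(obs)] <= 0):
            raise InvalidObservationError(
                f"{model.spec.name.value} observations must be positive"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            t_obs = np.where(np.isfinite(obs), model.spec.transform(np.where(np.isfinite(obs), obs, 1.0)), np.nan)
            z = (t_obs - mu) / sigma
        out["z"] = z
        out["percentile"] = 100.0 * stats.norm.cdf(z)
        label = np.where(z < -_Z90, "below_range", np.where(z > _Z90, "above_range", "within_range"))
        out["classification"] = np.where(np.isfinite(z), label, "missing")
    return out
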