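"""Maximum-likelihood fitting of the Gaussian location-scale model.

The model for one outcome is

    T(y_i) ~ Normal(mu_i, sigma_i)
    mu_i    = x_mu_i . a          (identity link)
    sigma_i = exp(x_sigma_i . b)  (log link)

with T the natural log for Raw/G/H and the identity for EELV.  The mu
design uses sqrt(mass); the sigma design uses untransformed mass; PEEP is
a categorical factor with level 0 cmH2O as the reference.  Observations
are treated as independent across animals and PEEP levels.

Estimation maximizes the exact Gaussian log-likelihood jointly in (a, b)
by alternating two exact/Newton steps:

* given b, the mu step is a weighted least-squares solve (the exact
  conditional maximizer);
* given a, the sigma step is a damped Newton update using the analytic
  gradient and Hessian of the profile in b.

Convergence requires both a relative log-likelihood change below ``tol_ll``
and a joint gradient max-norm below ``tol_grad``.  Standard errors come
from the observed information matrix at the optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DesignError
from .outcomes import PEEP_DUMMY_LEVELS, Outcome, OutcomeSpec, outcome_spec
from .reference import LocationScaleCoefficients, ReferenceModel

#: Cohort-table column holding each outcome.
OUTCOME_COLUMNS = {
    Outcome.RAW: "raw",
    Outcome.G: "g",
    Outcome.H: "h",
    Outcome.EELV: "eelv_ml",
}


@dataclass(frozen=True)
class DesignSpec:
    """Which terms enter each submodel.  Intercepts are always present."""

    outcome: OutcomeSpec
    mu_sqrt_mass: bool = True
    mu_strain: bool = True
    mu_sex: bool = True
    mu_peep: bool = True
    sigma_mass: bool = False
    sigma_strain: bool = False
    sigma_sex: bool = False
    sigma_peep: bool = False

    @property
    def n_parameters(self) -> int:
        return (
            2
            + sum((self.mu_sqrt_mass, self.mu_strain, self.mu_sex))
            + len(PEEP_DUMMY_LEVELS) * self.mu_peep
            + sum((self.sigma_mass, self.sigma_strain, self.sigma_sex))
            + len(PEEP_DUMMY_LEVELS) * self.sigma_peep
        )


def published_design(outcome: Outcome | str) -> DesignSpec:
    """The final published design for an outcome.

    All four mu terms are always included; the sigma terms differ by
    outcome (Raw: strain + PEEP; G: sex + PEEP; H: mass + sex;
    EELV: mass + strain + sex + PEEP).
    """
    out = Outcome(outcome)
    sigma_terms = {
        Outcome.RAW: dict(sigma_strain=True, sigma_peep=True),
        Outcome.G: dict(sigma_sex=True, sigma_peep=True),
        Outcome.H: dict(sigma_mass=True, sigma_sex=True),
        Outcome.EELV: dict(
            sigma_mass=True, sigma_strain=True, sigma_sex=True, sigma_peep=True
        ),
    }[out]
    return DesignSpec(outcome=outcome_spec(out), **sigma_terms)


def _peep_dummies(peep: np.ndarray) -> np.ndarray:
    return np.column_stack([(peep == lvl).astype(float) for lvl in PEEP_DUMMY_LEVELS])


def build_design(records: pd.DataFrame, spec: DesignSpec):
    """Assemble (mu design, sigma design, response) from a cohort table.

    The response is transformed onto the modelling scale.  Rows with a
    missing response are dropped; the count of dropped rows is returned.

    Returns
    -------
    X_mu, X_sigma : float arrays
    t_y : response on the modelling scale
    info : dict with ``mu_terms``, ``sigma_terms``, ``n_dropped``,
           ``index`` (surviving row index of ``records``) and ``y``
           (response in original units)
    """
    col = OUTCOME_COLUMNS[spec.outcome.name]
    y = pd.to_numeric(records[col], errors="coerce")
    keep = y.notna()
    n_dropped = int((~keep).sum())
    sub = records.loc[keep]
    if len(sub) == 0:
        raise DesignError(f"no usable rows: every {col!r} value is missing")
    y = y.loc[keep].to_numpy(float)
    mass = sub["mass_g"].to_numpy(float)
    wistar = (sub["strain"].astype(str) == "wistar").to_numpy(float)
    male = (sub["sex"].astype(str) == "male").to_numpy(float)
    peep = sub["peep_cmH2O"].to_numpy(int)
    one = np.ones(len(sub))

    mu_cols, mu_terms = [one], ["intercept"]
    if spec.mu_sqrt_mass:
        mu_cols.append(np.sqrt(mass)), mu_terms.append("sqrt_mass")
    if spec.mu_strain:
        mu_cols.append(wistar), mu_terms.append("strain_wistar")
    if spec.mu_sex:
        mu_cols.append(male), mu_terms.append("sex_male")
    if spec.mu_peep:
        mu_cols.append(_peep_dummies(peep))
        mu_terms += [f"peep_{lvl}" for lvl in PEEP_DUMMY_LEVELS]

    sig_cols, sig_terms = [one], ["intercept"]
    if spec.sigma_mass:
        sig_cols.append(mass), sig_terms.append("mass")
    if spec.sigma_strain:
        sig_cols.append(wistar), sig_terms.append("strain_wistar")
    if spec.sigma_sex:
        sig_cols.append(male), sig_terms.append("sex_male")
    if spec.sigma_peep:
        sig_cols.append(_peep_dummies(peep))
        sig_terms += [f"peep_{lvl}" for lvl in PEEP_DUMMY_LEVELS]

    X_mu = np.column_stack(mu_cols)
    X_sigma = np.column_stack(sig_cols)
    t_y = np.asarray(spec.outcome.transform(y), float)
    info = dict(
        mu_terms=mu_terms,
        sigma_terms=sig_terms,
        n_dropped=n_dropped,
        index=sub.index,
        y=y,
    )
    return X_mu, X_sigma, t_y, info


def _loglik(a, b, X_mu, X_sigma, t_y):
    mu = X_mu @ a
    eta = X_sigma @ b
    r = t_y - mu
    return float(
        -0.5 * len(t_y) * np.log(2 * np.pi) - eta.sum() - 0.5 * np.sum(r**2 * np.exp(-2 * eta))
    )


def _gradients(a, b, X_mu, X_sigma, t_y):
    mu = X_mu @ a
    s2 = np.exp(2 * (X_sigma @ b))
    r = t_y - mu
    u = r**2 / s2
    return X_mu.T @ (r / s2), X_sigma.T @ (u - 1.0)


def _observed_information(a, b, X_mu, X_sigma, t_y):
    """Negative Hessian of the log-likelihood at (a, b)."""
    mu = X_mu @ a
    s2 = np.exp(2 * (X_sigma @ b))
    r = t_y - mu
    u = r**2 / s2
    I_aa = (X_mu / s2[:, None]).T @ X_mu
    I_ab = 2.0 * (X_mu * (r / s2)[:, None]).T @ X_sigma
    I_bb = 2.0 * (X_sigma * u[:, None]).T @ X_sigma
    return np.block([[I_aa, I_ab], [I_ab.T, I_bb]])


@dataclass
class FittedModel:
    """Result of :func:`fit_location_scale`."""

    spec: DesignSpec
    coefficients: LocationScaleCoefficients
    mu_estimates: dict[str, float]
    sigma_estimates: dict[str, float]
    mu_standard_errors: dict[str, float]
    sigma_standard_errors: dict[str, float]
    log_likelihood: float
    n_obs: int
    n_dropped: int
    converged: bool
    n_iterations: int
    fitted_mu: np.ndarray = field(repr=False)
    fitted_sigma: np.ndarray = field(repr=False)
    residuals_fitting_scale: np.ndarray = field(repr=False)  # T(y) - mu_hat
    residuals_original_scale: np.ndarray = field(repr=False)  # y - back(mu_hat)
    standardized_residuals: np.ndarray = field(repr=False)
    r2_cox_snell: float | None = None

    @property
    def n_parameters(self) -> int:
        return self.spec.n_parameters

    def as_reference_model(self) -> ReferenceModel:
        """Package the fitted coefficients as a reference model."""
        return ReferenceModel(spec=self.spec.outcome, coefficients=self.coefficients)


def _coefficients_from_estimates(spec: DesignSpec, mu_est, sigma_est):
    mu_peep = {lvl: mu_est.get(f"peep_{lvl}", 0.0) for lvl in PEEP_DUMMY_LEVELS}
    mu_peep[0] = 0.0
    sigma_peep = None
    if spec.sigma_peep:
        sigma_peep = {lvl: sigma_est[f"peep_{lvl}"] for lvl in PEEP_DUMMY_LEVELS}
        sigma_peep[0] = 0.0
    return LocationScaleCoefficients(
        a0=mu_est["intercept"],
        a1=mu_est.get("sqrt_mass", 0.0),
        a2=mu_est.get("strain_wistar", 0.0),
        a3=mu_est.get("sex_male", 0.0),
        mu_peep_effects=mu_peep,
        b0=sigma_est["intercept"],
        b1=sigma_est.get("mass") if spec.sigma_mass else None,
        b2=sigma_est.get("strain_wistar") if spec.sigma_strain else None,
        b3=sigma_est.get("sex_male") if spec.sigma_sex else None,
        sigma_peep_effects=sigma_peep,
    )


def fit_location_scale(
    records: pd.DataFrame,
    spec: DesignSpec,
    tol_ll: float = 1e-10,
    tol_grad: float = 1e-6,
    max_iter: int = 500,
    compute_r2: bool = True,
) -> FittedModel:
    """Fit the location-scale model by joint maximum likelihood.

    Starting values: ordinary least squares for the mu coefficients and
    log of the OLS residual standard deviation (maximum-likelihood divisor
    n) for the sigma intercept, zeros elsewhere.

    Raises
    ------
    DesignError
        if the design is rank deficient or has more parameters than rows.
    """
    X_mu_raw, X_sigma_raw, t_y, info = build_design(records, spec)
    n = len(t_y)
    p = X_mu_raw.shape[1] + X_sigma_raw.shape[1]
    if n <= p:
        raise DesignError(f"{n} usable rows cannot identify {p} parameters")
    if np.linalg.matrix_rank(X_mu_raw) < X_mu_raw.shape[1] or np.linalg.matrix_rank(
        X_sigma_raw
    ) < X_sigma_raw.shape[1]:
        raise DesignError("rank-deficient design matrix")

    # fit with unit-scaled columns (mass enters the sigma design in grams,
    # which would otherwise dominate the gradient and the information matrix)
    scale_mu = np.maximum(np.max(np.abs(X_mu_raw), axis=0), 1e-12)
    scale_sigma = np.maximum(np.max(np.abs(X_sigma_raw), axis=0), 1e-12)
    X_mu = X_mu_raw / scale_mu
    X_sigma = X_sigma_raw / scale_sigma

    # starting values
    a, *_ = np.linalg.lstsq(X_mu, t_y, rcond=None)
    resid0 = t_y - X_mu @ a
    b = np.zeros(X_sigma.shape[1])
    b[0] = 0.5 * np.log(max(np.mean(resid0**2), 1e-300))

    ll = _loglik(a, b, X_mu, X_sigma, t_y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # exact mu step given sigma
        w = np.exp(-2 * (X_sigma @ b))
        Xw = X_mu * w[:, None]
        a = np.linalg.solve(X_mu.T @ Xw, Xw.T @ t_y)
        r = t_y - X_mu @ a
        # damped Newton step(s) for the sigma coefficients
        for _ in range(3):
            u = r**2 * np.exp(-2 * (X_sigma @ b))
            grad_b = X_sigma.T @ (u - 1.0)
            hess = 2.0 * (X_sigma * u[:, None]).T @ X_sigma
            try:
                step = np.linalg.solve(hess, grad_b)
            except np.linalg.LinAlgError:
                step = grad_b / (2.0 * n)
            scale = 1.0
            ll_b = _loglik(a, b, X_mu, X_sigma, t_y)
            for _ in range(30):
                cand = b + scale * step
                if _loglik(a, cand, X_mu, X_sigma, t_y) >= ll_b:
                    b = cand
                    break
                scale *= 0.5
            if np.max(np.abs(grad_b)) < 0.1 * tol_grad:
                break
        ll_new = _loglik(a, b, X_mu, X_sigma, t_y)
        ga, gb = _gradients(a, b, X_mu, X_sigma, t_y)
        grad_norm = max(np.max(np.abs(ga)), np.max(np.abs(gb)))
        # once the alternation is near the optimum, polish with joint Newton
        # steps (the alternation alone converges only linearly when the two
        # submodels are strongly coupled)
        if grad_norm < 1.0:
            theta = np.concatenate([a, b])
            p_mu = X_mu.shape[1]
            for _ in range(50):
                ga, gb = _gradients(theta[:p_mu], theta[p_mu:], X_mu, X_sigma, t_y)
                grad = np.concatenate([ga, gb])
                grad_norm = np.max(np.abs(grad))
                if grad_norm < tol_grad:
                    break
                info_mat = _observed_information(
                    theta[:p_mu], theta[p_mu:], X_mu, X_sigma, t_y
                )
                try:
                    step = np.linalg.solve(info_mat, grad)
                except np.linalg.LinAlgError:
                    break
                ll_cur = _loglik(theta[:p_mu], theta[p_mu:], X_mu, X_sigma, t_y)
                scale = 1.0
                for _ in range(30):
                    cand = theta + scale * step
                    if _loglik(cand[:p_mu], cand[p_mu:], X_mu, X_sigma, t_y) >= ll_cur:
                        theta = cand
                        break
                    scale *= 0.5
                else:
                    break
            a, b = theta[:p_mu], theta[p_mu:]
            ll_new = _loglik(a, b, X_mu, X_sigma, t_y)
        # the gradient scales with n (it sums over observations), so the
        # tolerance is scaled by the likelihood magnitude
        grad_ok = grad_norm < tol_grad * max(1.0, abs(ll_new))
        if abs(ll_new - ll) <= tol_ll * max(1.0, abs(ll_new)) and grad_ok:
            ll = ll_new
            converged = True
            break
        if ll_new == ll:  # float plateau: no further progress is possible
            break
        ll = ll_new

    # observed information at the optimum
    mu_hat = X_mu @ a
    s_hat = np.exp(X_sigma @ b)
    r = t_y - mu_hat
    s2 = s_hat**2
    u = r**2 / s2
    I_aa = (X_mu / s2[:, None]).T @ X_mu
    I_ab = 2.0 * (X_mu * (r / s2)[:, None]).T @ X_sigma
    I_bb = 2.0 * (X_sigma * u[:, None]).T @ X_sigma
    info_mat = np.block([[I_aa, I_ab], [I_ab.T, I_bb]])
    try:
        cov = np.linalg.inv(info_mat)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(p, np.nan)

    mu_terms, sig_terms = info["mu_terms"], info["sigma_terms"]
    mu_est = dict(zip(mu_terms, a / scale_mu))
    sigma_est = dict(zip(sig_terms, b / scale_sigma))
    mu_se = dict(zip(mu_terms, ses[: len(mu_terms)] / scale_mu))
    sigma_se = dict(zip(sig_terms, ses[len(mu_terms):] / scale_sigma))

    out = spec.outcome
    fitted = FittedModel(
        spec=spec,
        coefficients=_coefficients_from_estimates(spec, mu_est, sigma_est),
        mu_estimates=mu_est,
        sigma_estimates=sigma_est,
        mu_standard_errors=mu_se,
        sigma_standard_errors=sigma_se,
        log_likelihood=ll,
        n_obs=n,
        n_dropped=info["n_dropped"],
        converged=converged,
        n_iterations=it,
        fitted_mu=mu_hat,
        fitted_sigma=s_hat,
        residuals_fitting_scale=r,
        residuals_original_scale=info["y"] - np.asarray(out.back_transform(mu_hat)),
        standardized_residuals=r / s_hat,
    )
    if compute_r2:
        null_spec = DesignSpec(
            outcome=out,
            mu_sqrt_mass=False,
            mu_strain=False,
            mu_sex=False,
            mu_peep=False,
        )
        null_fit = fit_location_scale(records, null_spec, compute_r2=False)
        fitted.r2_cox_snell = cox_snell_r2(fitted, null_fit)
    return fitted


def cox_snell_r2(fitted: FittedModel, null_fitted: FittedModel) -> float:
    """Likelihood-ratio pseudo-R^2: 1 - exp((2/n)(l0 - l1)), in [0, 1)."""
    if fitted.n_obs != null_fitted.n_obs:
        raise DesignError(
            f"models fitted on different observation counts "
            f"({fitted.n_obs} vs {null_fitted.n_obs})"
        )
    n = fitted.n_obs
    return float(
        1.0 - np.exp((2.0 / n) * (null_fitted.log_likelihood - fitted.log_likelihood))
    )


def gaic(fitted: FittedModel, penalty: float = 2.0) -> float:
    """Generalized Akaike information criterion, -2*loglik + penalty*k.

    ``penalty = 2`` gives the ordinary AIC; ``penalty = 0`` returns the
    deviance -2*loglik.
    """
    return -2.0 * fitted.log_likelihood + penalty * fitted.n_parameters


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Moments of the residuals (observed - fitted on the modelling scale)
    and normal Q-Q points of the standardized residuals."""

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    qq_points: Sequence[tuple[float, float]]


def residual_diagnostics(fitted: FittedModel) -> ResidualDiagnostics:
    """Residual moments following the reporting convention of the published
    diagnostics table: residuals are observed minus fitted on the scale the
    model was fitted on (log for Raw/G/H, original for EELV)."""
    r = np.asarray(fitted.residuals_fitting_scale, float)
    n = len(r)
    if n < 4:
        raise DegenerateInputError(f"need at least 4 residuals for moments, got {n}")
    sd = float(np.std(r, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("residuals have zero variance; moments undefined")
    z = np.sort(fitted.standardized_residuals)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return ResidualDiagnostics(
        mean=float(np.mean(r)),
        sd=sd,
        skewness=float(stats.skew(r, bias=False)),
        excess_kurtosis=float(stats.kurtosis(r, bias=False)),
        qq_points=list(zip(theo.tolist(), z.tolist())),
    )
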