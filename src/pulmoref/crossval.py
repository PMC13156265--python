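"""Monte Carlo cross-validation of the location-scale reference models.

Each iteration draws a random 70/30 train-test split (by animal, so that
all PEEP rows of one animal stay on the same side of the split), refits
the model on the training portion and evaluates on the held-out portion:

* z-scores (T(y) - mu_hat)/sigma_hat on the modelling scale, pooled over
  all iterations' test sets for the mean/SD/range and coverage summaries;
* RMSE and MAE between measured and predicted values in original units
  (predictions back-transformed for log outcomes), summarized as
  mean/SD/range over iterations.

Coverage is the fraction of pooled z-scores within a symmetric bound:
|z| <= 1.645 for the central 90% and |z| <= 1.96 for the central 95% of
the reference distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DesignError
from .fit import DesignSpec, build_design, fit_location_scale

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    n_iterations: int = 50
    test_fraction: float = 0.30
    seed: int = 0
    split_unit: str = "animal"  # "animal" | "row"

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise DegenerateInputError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction}"
            )
        if self.split_unit not in ("animal", "row"):
            raise DegenerateInputError(f"unknown split_unit {self.split_unit!r}")


@dataclass(frozen=True)
class CVMetrics:
    z_mean: float
    z_sd: float
    z_range: tuple[float, float]
    coverage_90: float
    coverage_95: float
    rmse_mean: float
    rmse_sd: float
    rmse_range: tuple[float, float]
    mae_mean: float
    mae_sd: float
    mae_range: tuple[float, float]
    n_iterations_used: int
    n_iterations_failed: int
    n_test_z: int

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["z_range"] = list(self.z_range)
        d["rmse_range"] = list(self.rmse_range)
        d["mae_range"] = list(self.mae_range)
        return d


def coverage(z_values, bound: float) -> float:
    """Fraction of z-scores with |z| <= bound."""
    z = np.asarray(z_values, float)
    if z.size == 0:
        raise DegenerateInputError("cannot compute coverage of an empty set")
    return float(np.mean(np.abs(z) <= bound))


def rmse(measured, predicted) -> float:
    """Root mean squared error between measured and predicted values."""
    m, p = np.asarray(measured, float), np.asarray(predicted, float)
    if m.shape != p.shape:
        raise DegenerateInputError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size == 0:
        raise DegenerateInputError("cannot compute RMSE of empty vectors")
    return float(np.sqrt(np.mean((m - p) ** 2)))


def mae(measured, predicted) -> float:
    """Mean absolute error between measured and predicted values."""
    m, p = np.asarray(measured, float), np.asarray(predicted, float)
    if m.shape != p.shape:
        raise DegenerateInputError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size == 0:
        raise DegenerateInputError("cannot compute MAE of empty vectors")
    return float(np.mean(np.abs(m - p)))


def _split(records: pd.DataFrame, config: CVConfig, rng: np.random.Generator):
    if config.split_unit == "animal":
        ids = np.sort(records["animal_id"].unique())
        n_test = max(1, int(round(config.test_fraction * len(ids))))
        test_ids = set(rng.choice(ids, size=n_test, replace=False))
        mask = records["animal_id"].isin(test_ids)
    else:
        n_test = max(1, int(round(config.test_fraction * len(records))))
        idx = rng.choice(len(records), size=n_test, replace=False)
        mask = np.zeros(len(records), bool)
        mask[idx] = True
        mask = pd.Series(mask, index=records.index)
    return records.loc[~mask], records.loc[mask]


def monte_carlo_cv(
    records: pd.DataFrame, spec: DesignSpec, config: CVConfig = CVConfig()
) -> CVMetrics:
    """Run the Monte Carlo cross-validation and aggregate its metrics.

    Iterations whose training fit fails to converge (or whose design is
    unusable) are excluded from the aggregates; their count is logged and
    reported in the result, never silently averaged.
    """
    rng = np.random.default_rng(config.seed)
    pooled_z: list[np.ndarray] = []
    rmses: list[float] = []
    maes: list[float] = []
    failed = 0
    for _ in range(config.n_iterations):
        train, test = _split(records, config, rng)
        try:
            fitted = fit_location_scale(train, spec, compute_r2=False)
        except DesignError:
            failed += 1
            continue
        if not fitted.converged:
            failed += 1
            continue
        try:
            X_mu, X_sigma, t_y, info = build_design(test, spec)
        except DesignError:
            failed += 1
            continue
        a = np.array([fitted.mu_estimates[t] for t in info["mu_terms"]])
        b = np.array([fitted.sigma_estimates[t] for t in info["sigma_terms"]])
        mu_hat = X_mu @ a
        sigma_hat = np.exp(X_sigma @ b)
        pooled_z.append((t_y - mu_hat) / sigma_hat)
        predicted = np.asarray(spec.outcome.back_transform(mu_hat), float)
        rmses.append(rmse(info["y"], predicted))
        maes.append(mae(info["y"], predicted))
    used = config.n_iterations - failed
    if failed:
        logger.warning("%d of %d CV iterations excluded", failed, config.n_iterations)
    if used == 0:
        raise DegenerateInputError("every cross-validation iteration failed")
    z = np.concatenate(pooled_z)
    r_arr, m_arr = np.asarray(rmses), np.asarray(maes)
    return CVMetrics(
        z_mean=float(z.mean()),
        z_sd=float(z.std(ddof=1)),
        z_range=(float(z.min()), float(z.max())),
        coverage_90=coverage(z, 1.645),
        coverage_95=coverage(z, 1.96),
        rmse_mean=float(r_arr.mean()),
        rmse_sd=float(r_arr.std(ddof=1)) if used > 1 else 0.0,
        rmse_range=(float(r_arr.min()), float(r_arr.max())),
        mae_mean=float(m_arr.mean()),
        mae_sd=float(m_arr.std(ddof=1)) if used > 1 else 0.0,
        mae_range=(float(m_arr.min()), float(m_arr.max())),
        n_iterations_used=used,
        n_iterations_failed=failed,
        n_test_z=int(z.size),
    )
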