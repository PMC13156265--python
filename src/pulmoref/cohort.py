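"""Synthetic rat cohorts with the covariate structure of the study.

The study cohort comprises four strain-by-sex groups of Sprague Dawley and
Wistar rats whose body-mass distributions are right-skewed and summarized
only by median and min-max range.  The generator draws masses from a
log-normal distribution truncated to the printed range, with its location
at log(median) (median-preserving before truncation) and its scale set so
that the central 95% of the untruncated distribution roughly spans the
printed range.  Outcomes are then drawn from a Gaussian location-scale
reference model on the modelling scale — T(y) ~ Normal(mu, sigma) with T
the natural log for Raw/G/H and identity for EELV — independently across
PEEP levels within an animal, matching the final published model, which
carries no random animal effect.

EELV at the highest PEEP can be set missing with a configurable
probability, emulating animals that made no breathing effort against the
occlusion at high PEEP.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidCovariateError, SchemaError
from .outcomes import PEEP_LEVELS, Outcome, Sex, Strain
from .reference import ReferenceModel, default_models, mu_sigma_arrays

#: Canonical cohort-table column order.
COHORT_COLUMNS = [
    "animal_id",
    "strain",
    "sex",
    "mass_g",
    "peep_cmH2O",
    "raw",
    "g",
    "h",
    "eelv_ml",
]


@dataclass(frozen=True)
class GroupMassSpec:
    """Body-mass summary of one strain-by-sex group (grams)."""

    strain: Strain
    sex: Sex
    n: int
    median_g: float
    min_g: float
    max_g: float

    def __post_init__(self):
        object.__setattr__(self, "strain", Strain(self.strain))
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.n <= 0:
            raise InvalidCovariateError(f"group size must be positive, got {self.n}")
        if not (0 < self.min_g < self.median_g < self.max_g):
            raise InvalidCovariateError(
                f"need 0 < min < median < max, got "
                f"({self.min_g}, {self.median_g}, {self.max_g})"
            )


#: Printed study group sizes and mass summaries.
DEFAULT_GROUPS = (
    GroupMassSpec(Strain.SPRAGUE_DAWLEY, Sex.MALE, n=52, median_g=317, min_g=170, max_g=750),
    GroupMassSpec(Strain.SPRAGUE_DAWLEY, Sex.FEMALE, n=46, median_g=258, min_g=164, max_g=376),
    GroupMassSpec(Strain.WISTAR, Sex.MALE, n=53, median_g=310, min_g=156, max_g=530),
    GroupMassSpec(Strain.WISTAR, Sex.FEMALE, n=31, median_g=260, min_g=162, max_g=366),
)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort deterministically."""

    group_specs: tuple[GroupMassSpec, ...] = DEFAULT_GROUPS
    peep_levels: tuple[int, ...] = PEEP_LEVELS
    seed: int = 0
    p_missing_eelv_top_peep: float = 0.0

    def __post_init__(self):
        bad = sorted(set(self.peep_levels) - set(PEEP_LEVELS))
        if bad:
            raise InvalidCovariateError(f"unknown PEEP levels {bad}")
        if not 0.0 <= self.p_missing_eelv_top_peep <= 1.0:
            raise InvalidCovariateError("p_missing_eelv_top_peep must lie in [0, 1]")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def sample_body_mass(spec: GroupMassSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``spec.n`` body masses (grams) from the truncated log-normal.

    All samples lie in [min_g, max_g]; the distribution is right-skewed on
    the gram scale and its median stays close to ``median_g``.
    """
    log_min, log_med, log_max = (
        np.log(spec.min_g),
        np.log(spec.median_g),
        np.log(spec.max_g),
    )
    scale = (log_max - log_min) / (2 * 1.96)
    a = (log_min - log_med) / scale
    b = (log_max - log_med) / scale
    dist = stats.truncnorm(a, b, loc=log_med, scale=scale)
    return np.exp(dist.ppf(rng.uniform(size=spec.n)))


def _animal_frame(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counter = 0
    for spec in config.group_specs:
        masses = sample_body_mass(spec, rng)
        for m in masses:
            counter += 1
            rows.append(
                dict(
                    animal_id=f"rat{counter:04d}",
                    strain=spec.strain.value,
                    sex=spec.sex.value,
                    mass_g=float(m),
                )
            )
    return pd.DataFrame(rows)


def generate_measurements(
    animals: pd.DataFrame,
    models: dict[Outcome, ReferenceModel] | None = None,
    rng: np.random.Generator | None = None,
    peep_levels: tuple[int, ...] = PEEP_LEVELS,
    p_missing_eelv_top_peep: float = 0.0,
) -> pd.DataFrame:
    """Expand an animal table to animal x PEEP rows with simulated outcomes.

    For each outcome, T(y) ~ Normal(mu(cov), sigma(cov)) on the modelling
    scale, back-transformed to original units (exponentiation keeps
    Raw/G/H strictly positive).  EELV at the highest requested PEEP is set
    missing with probability ``p_missing_eelv_top_peep`` per animal.
    """
    if models is None:
        models = default_models()
    if rng is None:
        rng = np.random.default_rng()
    peep_levels = tuple(sorted(peep_levels))
    long = animals.loc[animals.index.repeat(len(peep_levels))].reset_index(drop=True)
    long["peep_cmH2O"] = np.tile(peep_levels, len(animals))
    for outcome, col in (
        (Outcome.RAW, "raw"),
        (Outcome.G, "g"),
        (Outcome.H, "h"),
        (Outcome.EELV, "eelv_ml"),
    ):
        model = models[outcome]
        mu, sigma = mu_sigma_arrays(model, long)
        t_y = rng.normal(mu, sigma)
        long[col] = np.asarray(model.spec.back_transform(t_y), float)
    if p_missing_eelv_top_peep > 0:
        top = long["peep_cmH2O"] == max(peep_levels)
        drop = rng.uniform(size=len(long)) < p_missing_eelv_top_peep
        long.loc[top & drop, "eelv_ml"] = np.nan
    return long[COHORT_COLUMNS]


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    models: dict[Outcome, ReferenceModel] | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic cohort table from a config (seeded)."""
    rng = np.random.default_rng(config.seed)
    animals = _animal_frame(config, rng)
    return generate_measurements(
        animals,
        models=models,
        rng=rng,
        peep_levels=config.peep_levels,
        p_missing_eelv_top_peep=config.p_missing_eelv_top_peep,
    )


# -- cohort table I/O ------------------------------------------------------
_VALID_STRAINS = {s.value for s in Strain}
_VALID_SEXES = {s.value for s in Sex}


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort table as comma-separated text (empty cell = missing)."""
    frame.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table written by :func:`write_cohort`."""
    frame = pd.read_csv(path)
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"cohort table missing columns {missing_cols}", missing_cols)
    violations = validate_table(frame)
    if violations:
        first = violations[0]
        raise SchemaError(
            f"invalid cohort table ({len(violations)} violation(s)); first: "
            f"row {first[0]}, column {first[1]}: {first[2]}",
            [f"{r}:{c}" for r, c, _ in violations],
        )
    return frame[COHORT_COLUMNS]


def validate_table(frame: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Check a cohort table row by row; returns (row, column, message) triples.

    Never mutates its input.  Checks enum domains (strain, sex, PEEP level),
    positivity of mass and of the log-scale outcomes; missing outcome cells
    are allowed.
    """
    problems: list[tuple[int, str, str]] = []
    for idx, row in frame.iterrows():
        if str(row.get("strain")) not in _VALID_STRAINS:
            problems.append((idx, "strain", f"unknown strain {row.get('strain')!r}"))
        if str(row.get("sex")) not in _VALID_SEXES:
            problems.append((idx, "sex", f"unknown sex {row.get('sex')!r}"))
        mass = pd.to_numeric(pd.Series([row.get("mass_g")]), errors="coerce").iloc[0]
        if not (pd.notna(mass) and mass > 0):
            problems.append((idx, "mass_g", f"mass must be positive, got {row.get('mass_g')!r}"))
        peep = pd.to_numeric(pd.Series([row.get("peep_cmH2O")]), errors="coerce").iloc[0]
        if pd.isna(peep) or int(peep) != peep or int(peep) not in PEEP_LEVELS:
            problems.append(
                (idx, "peep_cmH2O", f"PEEP must be one of {PEEP_LEVELS}, got {row.get('peep_cmH2O')!r}")
            )
        for col in ("raw", "g", "h"):
            val = pd.to_numeric(pd.Series([row.get(col)]), errors="coerce").iloc[0]
            if pd.notna(val) and val <= 0:
                problems.append((idx, col, f"{col} must be positive, got {val!r}"))
    return problems
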