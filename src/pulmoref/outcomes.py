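"""Outcome definitions and covariate coding for the rat lung-function
reference framework.

Four outcomes are modelled: airway resistance (Raw), tissue damping (G),
tissue elastance (H) and end-expiratory lung volume (EELV).  Raw, G and H
are right-skewed and are modelled on the natural-log scale; EELV is
modelled untransformed.  Covariates are body mass (grams), strain
(Sprague Dawley / Wistar), sex, and the ventilator PEEP level, which takes
one of six discrete values (0, 1, 2, 3, 4, 6 cmH2O).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import InvalidCovariateError

PEEP_LEVELS = (0, 1, 2, 3, 4, 6)
#: PEEP levels that enter the design as dummies (level 0 is the reference).
PEEP_DUMMY_LEVELS = (1, 2, 3, 4, 6)


class Outcome(str, Enum):
    RAW = "raw"
    G = "g"
    H = "h"
    EELV = "eelv"


class Strain(str, Enum):
    SPRAGUE_DAWLEY = "sprague_dawley"
    WISTAR = "wistar"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


#: Measurement units per outcome.
UNITS = {
    Outcome.RAW: "cmH2O.s/l",
    Outcome.G: "cmH2O/l",
    Outcome.H: "cmH2O/l",
    Outcome.EELV: "ml",
}


@dataclass(frozen=True)
class OutcomeSpec:
    """What is being modelled and on which scale.

    ``mu_transform`` is ``"log"`` for Raw, G and H (the Gaussian
    location-scale model is fitted to the natural log of the outcome) and
    ``"identity"`` for EELV.
    """

    name: Outcome
    units: str
    mu_transform: str  # "log" | "identity"

    def transform(self, y):
        """Map observed values in original units onto the modelling scale."""
        if self.mu_transform == "log":
            return np.log(y)
        return np.asarray(y, dtype=float) if np.ndim(y) else float(y)

    def back_transform(self, t):
        """Inverse of :meth:`transform` (original units)."""
        if self.mu_transform == "log":
            return np.exp(t)
        return np.asarray(t, dtype=float) if np.ndim(t) else float(t)


def outcome_spec(outcome: Outcome | str) -> OutcomeSpec:
    """Return the canonical :class:`OutcomeSpec` for an outcome name."""
    out = Outcome(outcome)
    transform = "identity" if out is Outcome.EELV else "log"
    return OutcomeSpec(name=out, units=UNITS[out], mu_transform=transform)


@dataclass(frozen=True)
class CovariateSet:
    """One animal-measurement covariate combination.

    ``mass_g`` is body mass in grams.  The indicator coding matches the
    published equations: I_Wistar = 1 for Wistar (0 for Sprague Dawley),
    I_male = 1 for males.
    """

    mass_g: float
    strain: Strain
    sex: Sex
    peep_cmH2O: int

    def __post_init__(self):
        object.__setattr__(self, "strain", Strain(self.strain))
        object.__setattr__(self, "sex", Sex(self.sex))
        if not (np.isfinite(self.mass_g) and self.mass_g > 0):
            raise InvalidCovariateError(f"body mass must be positive, got {self.mass_g!r}")
        if self.peep_cmH2O not in PEEP_LEVELS:
            raise InvalidCovariateError(
                f"unknown PEEP level {self.peep_cmH2O!r}; study levels are {PEEP_LEVELS}"
            )

    @property
    def i_wistar(self) -> int:
        return int(self.strain is Strain.WISTAR)

    @property
    def i_male(self) -> int:
        return int(self.sex is Sex.MALE)
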