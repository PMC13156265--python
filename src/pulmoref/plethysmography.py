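"""End-expiratory lung volume from occluded-breathing plethysmography.

With the trachea occluded at end-expiration, spontaneous inspiratory
efforts decompress the thoracic gas: tracheal pressure falls while the
chest expands, compressing the gas in the sealed body box.  For pressure
swings small against atmospheric pressure, Boyle-Mariotte gives

    EELV = -s * beta * (Vbox - Vrat) - Vds,

where s = dPbox/dPtrach is the slope of box versus tracheal pressure
during efforts, beta = (Patm - PH2O)/Patm corrects for water vapour at
body temperature in alveolar gas, Vbox is the chamber volume, Vrat the
animal's volume (body mass over an average body density of 1.025 g/cm3)
and Vds the instrumental dead space of the tracheal cannula.

The slope comes from a linear regression of Pbox on Ptrach restricted to
effort samples; a threshold on the tracheal deflection excludes
cardiogenic oscillations, and the regression's r-squared verifies
linearity before an EELV value is reported.  A trace simulator inverts
the relation for testing and demonstration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, InvalidCovariateError, SchemaError

#: Instrument dead space (ml) by tracheal-cannula outer diameter (mm).
DEFAULT_V_DS_ML = {2.0: 0.53, 2.5: 0.65}


@dataclass(frozen=True)
class OcclusionTrace:
    """Paired tracheal/box pressure time series during one occlusion."""

    time_s: np.ndarray
    p_trach: np.ndarray
    p_box: np.ndarray
    sampling_rate_hz: float = 256.0

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        pt = np.asarray(self.p_trach, float)
        pb = np.asarray(self.p_box, float)
        if not (len(t) == len(pt) == len(pb)):
            raise SchemaError("time, tracheal and box series must have equal length")
        if len(t) == 0:
            raise DegenerateInputError("empty occlusion trace")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "p_trach", pt)
        object.__setattr__(self, "p_box", pb)


@dataclass(frozen=True)
class PlethysmographConfig:
    """Chamber geometry and physical constants.

    ``p_atm`` and ``p_h2o`` may be in any common pressure unit as long as
    both use the same one; only their ratio enters the computation.
    Defaults are standard-physiology values (760 mmHg barometric pressure,
    47 mmHg water vapour pressure at 37 degrees C).
    """

    v_box_ml: float = 1910.0
    p_atm: float = 760.0
    p_h2o: float = 47.0
    body_density_g_per_cm3: float = 1.025
    v_ds_ml: dict = field(default_factory=lambda: dict(DEFAULT_V_DS_ML))

    def __post_init__(self):
        if self.p_atm <= 0 or self.p_h2o < 0:
            raise InvalidCovariateError("pressures must be positive")
        if self.p_h2o >= self.p_atm:
            raise InvalidCovariateError(
                f"water vapour pressure ({self.p_h2o}) must be below "
                f"atmospheric pressure ({self.p_atm})"
            )
        if self.v_box_ml <= 0 or self.body_density_g_per_cm3 <= 0:
            raise InvalidCovariateError("volumes and densities must be positive")


@dataclass(frozen=True)
class EELVResult:
    """Outcome of one occlusion analysis.

    ``eelv_ml`` is NaN when the linearity check fails or the volume is
    non-physical (negative); ``valid`` states whether it may be used.
    """

    slope_s: float
    r2_linearity: float
    eelv_ml: float
    n_points_used: int
    valid: bool
    reason: str = ""


def beta_factor(config: PlethysmographConfig) -> float:
    """Water-vapour correction beta = (Patm - PH2O)/Patm, in (0, 1]."""
    return (config.p_atm - config.p_h2o) / config.p_atm


def detect_effort_samples(trace: OcclusionTrace, threshold="auto") -> np.ndarray:
    """Indices of inspiratory-effort samples in a trace.

    The tracheal signal is baseline-corrected (baseline = trace median,
    robust because efforts occupy a minority of samples); inspiratory
    efforts pull tracheal pressure below baseline, so samples with
    deflection below ``-threshold`` are selected.  ``threshold="auto"``
    uses 20% of the maximal deflection, which rejects the much smaller
    cardiogenic oscillations.
    """
    pt = trace.p_trach
    baseline = float(np.median(pt))
    deflection = pt - baseline
    max_defl = -float(deflection.min())
    if threshold == "auto":
        if max_defl <= 0:
            raise DegenerateInputError("no inspiratory deflection in trace")
        thr = 0.20 * max_defl
    else:
        thr = float(threshold)
    idx = np.flatnonzero(deflection < -thr)
    if idx.size == 0:
        raise DegenerateInputError(
            f"no samples exceed the effort threshold ({thr:g} cmH2O); "
            "occlusion unusable (no breathing effort)"
        )
    return idx


def regress_box_vs_tracheal(trace: OcclusionTrace, indices) -> tuple[float, float, float]:
    """Least-squares slope of Pbox on Ptrach over the selected samples.

    Returns (slope, intercept, r_squared); r_squared serves as the
    linearity check of the Pbox-Ptrach relationship.
    """
    idx = np.asarray(indices, int)
    if idx.size < 3:
        raise DegenerateInputError(f"need at least 3 samples, got {idx.size}")
    x = trace.p_trach[idx]
    y = trace.p_box[idx]
    if np.var(x) == 0:
        raise DegenerateInputError("tracheal pressure has zero variance over selection")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _v_ds(config: PlethysmographConfig, cannula_mm: float) -> float:
    try:
        return config.v_ds_ml[float(cannula_mm)]
    except KeyError:
        raise InvalidCovariateError(
            f"unknown cannula {cannula_mm!r}; known sizes: {sorted(config.v_ds_ml)}"
        ) from None


def compute_eelv(
    slope: float,
    config: PlethysmographConfig,
    mass_g: float,
    cannula_mm: float,
) -> tuple[float, bool]:
    """EELV (ml) from the Pbox/Ptrach slope via Boyle-Mariotte.

    Returns (eelv_ml, valid); a negative volume is returned but flagged
    invalid.
    """
    if mass_g <= 0:
        raise InvalidCovariateError(f"mass must be positive, got {mass_g}")
    v_rat = mass_g / config.body_density_g_per_cm3
    if v_rat >= config.v_box_ml:
        raise InvalidCovariateError(
            f"animal volume {v_rat:.0f} ml does not fit the {config.v_box_ml:.0f} ml box"
        )
    eelv = -slope * beta_factor(config) * (config.v_box_ml - v_rat) - _v_ds(config, cannula_mm)
    return float(eelv), eelv > 0


def eelv_from_trace(
    trace: OcclusionTrace,
    config: PlethysmographConfig,
    mass_g: float,
    cannula_mm: float,
    threshold="auto",
    r2_min: float = 0.95,
) -> EELVResult:
    """Full occlusion analysis: effort detection, regression, linearity
    check, Boyle-Mariotte volume."""
    idx = detect_effort_samples(trace, threshold)
    slope, _, r2 = regress_box_vs_tracheal(trace, idx)
    eelv, positive = compute_eelv(slope, config, mass_g, cannula_mm)
    if r2 < r2_min:
        return EELVResult(slope, r2, float("nan"), idx.size, False,
                          f"Pbox-Ptrach linearity check failed (r2={r2:.3f} < {r2_min})")
    if not positive:
        return EELVResult(slope, r2, float("nan"), idx.size, False,
                          f"non-physical volume ({eelv:.2f} ml)")
    return EELVResult(slope, r2, eelv, idx.size, True)


def implied_slope(
    eelv_true_ml: float,
    config: PlethysmographConfig,
    mass_g: float,
    cannula_mm: float,
) -> float:
    """Invert the Boyle-Mariotte relation: the slope a given EELV implies."""
    v_rat = mass_g / config.body_density_g_per_cm3
    return -(eelv_true_ml + _v_ds(config, cannula_mm)) / (
        beta_factor(config) * (config.v_box_ml - v_rat)
    )


def simulate_occlusion(
    eelv_true_ml: float,
    config: PlethysmographConfig,
    mass_g: float,
    cannula_mm: float,
    effort_amplitude_cmH2O: float = 10.0,
    n_efforts: int = 6,
    cardiogenic_amplitude_cmH2O: float = 0.0,
    sensor_noise_sd_cmH2O: float = 0.0,
    rng: np.random.Generator | None = None,
    duration_s: float = 12.0,
    sampling_rate_hz: float = 256.0,
) -> OcclusionTrace:
    """Synthesize an occlusion trace whose analysis should recover
    ``eelv_true_ml``.

    The trace holds a 2 s pre-occlusion baseline followed by sinusoid-like
    inspiratory efforts (negative tracheal deflections).  Box pressure
    follows the effort component of tracheal pressure through the implied
    linear slope; a cardiogenic ripple (added to the tracheal signal only,
    emulating heartbeat artefacts at ~5 Hz) and independent sensor noise on
    both channels are optional.
    """
    if eelv_true_ml <= 0:
        raise InvalidCovariateError(f"eelv_true_ml must be positive, got {eelv_true_ml}")
    if rng is None:
        rng = np.random.default_rng()
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    p_effort = np.zeros(n)
    effort_dur = 0.5  # s, one inspiratory effort
    start = 2.0
    spacing = (duration_s - start - effort_dur) / max(n_efforts - 1, 1)
    for j in range(n_efforts):
        t0 = start + j * spacing
        local = (t - t0) / effort_dur
        mask = (local >= 0) & (local <= 1)
        p_effort[mask] -= effort_amplitude_cmH2O * np.sin(np.pi * local[mask])
    s = implied_slope(eelv_true_ml, config, mass_g, cannula_mm)
    p_box = s * p_effort
    p_trach = p_effort.copy()
    if cardiogenic_amplitude_cmH2O > 0:
        phase = rng.uniform(0, 2 * np.pi)
        p_trach += cardiogenic_amplitude_cmH2O * np.sin(2 * np.pi * 5.0 * t + phase)
    if sensor_noise_sd_cmH2O > 0:
        p_trach = p_trach + rng.normal(0, sensor_noise_sd_cmH2O, n)
        p_box = p_box + rng.normal(0, sensor_noise_sd_cmH2O * abs(s), n)
    return OcclusionTrace(time_s=t, p_trach=p_trach, p_box=p_box,
                          sampling_rate_hz=sampling_rate_hz)


# -- trace file I/O --------------------------------------------------------
def write_trace(trace: OcclusionTrace, path) -> None:
    """Write a trace as delimited text (time_s, p_trach_cmH2O, p_box_cmH2O)."""
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "p_trach_cmH2O": trace.p_trach,
            "p_box_cmH2O": trace.p_box,
        }
    ).to_csv(path, index=False)


def read_trace(path, sampling_rate_hz: float = 256.0) -> OcclusionTrace:
    """Read a trace written by :func:`write_trace`."""
    frame = pd.read_csv(path)
    missing = [c for c in ("time_s", "p_trach_cmH2O", "p_box_cmH2O") if c not in frame.columns]
    if missing:
        raise SchemaError(f"trace file missing columns {missing}", missing)
    return OcclusionTrace(
        time_s=frame["time_s"].to_numpy(float),
        p_trach=frame["p_trach_cmH2O"].to_numpy(float),
        p_box=frame["p_box_cmH2O"].to_numpy(float),
        sampling_rate_hz=sampling_rate_hz,
    )
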