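"""Constant-phase model of respiratory input impedance.

The respiratory system's input impedance over the forced-oscillation
band is described by

    Zrs(f) = Raw + i*omega*Iaw + (G - i*H) / omega**alpha

with omega = 2*pi*f, airway (Newtonian) resistance Raw and inertance Iaw,
tissue damping G and tissue elastance H, and the constant-phase exponent
alpha = (2/pi)*atan(H/G).  The tissue compartment has a frequency-
independent phase, hence the model's name.

Fitting minimizes the relative modulus error

    sum_k |Z_meas(f_k) - Z_model(f_k)|^2 / |Z_meas(f_k)|^2

over (Raw, Iaw, G, H) with Raw, Iaw >= 0 and G, H > 0 (log-parameterized),
matching how measured spectra spanning orders of magnitude are weighted in
practice.  Helpers for equipment-impedance subtraction and ensemble
averaging of repeated recordings are included.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DegenerateInputError, InvalidCovariateError, SchemaError

_TWO_OVER_PI = 2.0 / np.pi


def _default_components(base_hz: float = 0.25, k_min: int = 2, k_max: int = 83):
    """Greedy non-harmonic selection of multiples of the base frequency.

    Scanning k = k_min..k_max in ascending order, keep k*base_hz whenever k
    neither divides nor is divided by any previously kept multiplier.  With
    the defaults this yields 23 components in [0.5, 20.75] Hz, none an
    integer multiple of another.
    """
    kept: list[int] = []
    for k in range(k_min, k_max + 1):
        if all(k % m and m % k for m in kept):
            kept.append(k)
    return np.array([k * base_hz for k in kept])


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered positive frequencies (Hz) used for forcing and fitting."""

    frequencies_hz: np.ndarray
    base_hz: float = 0.25

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, float)
        if f.size == 0 or np.any(f <= 0):
            raise InvalidCovariateError("frequencies must be positive and non-empty")
        if np.any(np.diff(f) <= 0):
            raise InvalidCovariateError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", f)

    @classmethod
    def default(cls) -> "FrequencyGrid":
        """The 23-component non-harmonic grid spanning 0.5-20.75 Hz."""
        return cls(_default_components())

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, 2*pi*f (rad/s)."""
        return 2.0 * np.pi * self.frequencies_hz

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    def matches(self, other: "FrequencyGrid") -> bool:
        return len(self) == len(other) and np.allclose(
            self.frequencies_hz, other.frequencies_hz
        )


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex input impedance (cmH2O.s/l) on a frequency grid."""

    grid: FrequencyGrid
    z_values: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z_values, complex)
        if len(z) != len(self.grid):
            raise SchemaError(
                f"{len(z)} impedance values for {len(self.grid)} frequencies"
            )
        object.__setattr__(self, "z_values", z)


@dataclass(frozen=True)
class ConstantPhaseParams:
    """Parameters of the constant-phase model.

    ``alpha`` is a derived quantity, always recomputed from H/G.
    """

    raw: float  # cmH2O.s/l
    iaw: float  # cmH2O.s^2/l
    g: float  # cmH2O/l
    h: float  # cmH2O/l

    def __post_init__(self):
        if self.raw < 0 or self.iaw < 0:
            raise InvalidCovariateError("raw and iaw must be non-negative")
        if self.g <= 0 or self.h <= 0:
            raise InvalidCovariateError("g and h must be strictly positive")

    @property
    def alpha(self) -> float:
        return alpha_from_gh(self.g, self.h)


@dataclass(frozen=True)
class FitQuality:
    relative_rms_error: float
    converged: bool
    n_freq: int


def alpha_from_gh(g: float, h: float) -> float:
    """Constant-phase exponent alpha = (2/pi)*atan(h/g), in (0, 1)."""
    if g <= 0 or h <= 0:
        raise InvalidCovariateError(f"g and h must be positive, got g={g}, h={h}")
    return _TWO_OVER_PI * np.arctan(h / g)


def model_impedance(params: ConstantPhaseParams, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate the constant-phase model on a frequency grid."""
    w = grid.omega
    z = params.raw + 1j * w * params.iaw + (params.g - 1j * params.h) / w**params.alpha
    return ImpedanceSpectrum(grid=grid, z_values=z)


def subtract_reference_impedance(
    spectrum: ImpedanceSpectrum, equipment_spectrum: ImpedanceSpectrum
) -> ImpedanceSpectrum:
    """Remove the separately measured equipment impedance (elementwise)."""
    if not spectrum.grid.matches(equipment_spectrum.grid):
        raise SchemaError("spectrum grids do not match")
    return ImpedanceSpectrum(
        grid=spectrum.grid, z_values=spectrum.z_values - equipment_spectrum.z_values
    )


def ensemble_average(spectra: list[ImpedanceSpectrum]) -> ImpedanceSpectrum:
    """Complex mean of repeated recordings on a common grid."""
    if not spectra:
        raise DegenerateInputError("cannot average an empty list of spectra")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if not grid.matches(s.grid):
            raise SchemaError("spectrum grids do not match")
    stacked = np.stack([s.z_values for s in spectra])
    return ImpedanceSpectrum(grid=grid, z_values=stacked.mean(axis=0))


def _initial_guess(spectrum: ImpedanceSpectrum) -> ConstantPhaseParams:
    """Asymptote-based starting values.

    At high frequency the tissue term vanishes, so Raw ~ Re(Z) there; at
    the lowest frequency the tissue term dominates, giving G and H from the
    real/imaginary parts after removing Raw, with alpha seeded at 0.8.
    """
    z = spectrum.z_values
    w = spectrum.grid.omega
    raw0 = max(float(np.real(z[-1])), 0.0)
    alpha0 = 0.8
    w0 = w[0]
    g0 = max((float(np.real(z[0])) - raw0) * w0**alpha0, 1e-6)
    h0 = max(-float(np.imag(z[0])) * w0**alpha0, 1e-6)
    iaw0 = max(float(np.imag(z[-1]) + h0 / w[-1] ** alpha_from_gh(g0, h0)) / w[-1], 0.0)
    return ConstantPhaseParams(raw=raw0, iaw=iaw0, g=g0, h=h0)


def fit_constant_phase(
    spectrum: ImpedanceSpectrum,
    init: ConstantPhaseParams | None = None,
) -> tuple[ConstantPhaseParams, FitQuality]:
    """Fit the constant-phase model to a measured spectrum.

    Minimizes the summed squared relative modulus error with Raw, Iaw
    bounded at zero and G, H kept positive through a log parameterization.
    ``relative_rms_error`` in the returned quality is the square root of
    the mean relative squared error over frequencies.
    """
    if len(spectrum.grid) < 4:
        raise DegenerateInputError(
            f"need at least 4 frequencies for 4 parameters, got {len(spectrum.grid)}"
        )
    z_meas = spectrum.z_values
    mod = np.abs(z_meas)
    if np.any(mod == 0):
        raise DegenerateInputError("spectrum contains zero-modulus values")
    w = spectrum.grid.omega
    if init is None:
        init = _initial_guess(spectrum)

    def residuals(x):
        raw, iaw, log_g, log_h = x
        g, h = np.exp(log_g), np.exp(log_h)
        alpha = _TWO_OVER_PI * np.arctan(h / g)
        z_mod = raw + 1j * w * iaw + (g - 1j * h) / w**alpha
        d = (z_mod - z_meas) / mod
        return np.concatenate([d.real, d.imag])

    x0 = np.array([init.raw, init.iaw, np.log(init.g), np.log(init.h)])
    lower = np.array([0.0, 0.0, -np.inf, -np.inf])
    upper = np.full(4, np.inf)
    sol = least_squares(
        residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    raw, iaw, log_g, log_h = sol.x
    params = ConstantPhaseParams(
        raw=float(raw), iaw=float(iaw), g=float(np.exp(log_g)), h=float(np.exp(log_h))
    )
    rel_rms = float(np.sqrt(np.mean(np.abs(residuals(sol.x)[: len(w)] + 1j * residuals(sol.x)[len(w):]) ** 2)))
    quality = FitQuality(
        relative_rms_error=rel_rms, converged=bool(sol.success), n_freq=len(w)
    )
    return params, quality


# -- spectrum file I/O -----------------------------------------------------
def write_spectrum(spectrum: ImpedanceSpectrum, path) -> None:
    """Write a spectrum as delimited text (frequency_hz, z_real, z_imag)."""
    pd.DataFrame(
        {
            "frequency_hz": spectrum.grid.frequencies_hz,
            "z_real": spectrum.z_values.real,
            "z_imag": spectrum.z_values.imag,
        }
    ).to_csv(path, index=False)


def read_spectrum(path) -> ImpedanceSpectrum:
    """Read a spectrum written by :func:`write_spectrum`."""
    frame = pd.read_csv(path)
    missing = [c for c in ("frequency_hz", "z_real", "z_imag") if c not in frame.columns]
    if missing:
        raise SchemaError(f"spectrum file missing columns {missing}", missing)
    grid = FrequencyGrid(frame["frequency_hz"].to_numpy(float))
    return ImpedanceSpectrum(
        grid=grid,
        z_values=frame["z_real"].to_numpy(float) + 1j * frame["z_imag"].to_numpy(float),
    )
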