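"""Spectral smoothing and target standardization.

Reflectance spectra are denoised with a Savitzky-Golay filter (local
least-squares polynomial, applied per sample along the band axis with
polynomial-interpolation edge handling so the band axis keeps its length
and wavelength alignment). Analyte concentrations, which span two orders of
magnitude across the panel, are z-scored before regression; the fitted
center/scale is kept so predictions can be mapped back to umol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import ConfigurationError, ZeroVarianceError

__all__ = [
    "SmoothingConfig",
    "Standardizer",
    "savgol_smooth",
    "standardize_fit_apply",
    "standardize_invert",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay settings: odd window (channels) and polynomial order."""

    window_length: int = 11
    polyorder: int = 2
    enabled: bool = True

    def __post_init__(self):
        if self.window_length % 2 == 0 or self.window_length < 3:
            raise ConfigurationError("window_length must be odd and >= 3")
        # polyorder == window_length - 1 would reproduce the input exactly;
        # require at least one degree of freedom for actual smoothing
        if not (0 <= self.polyorder <= self.window_length - 2):
            raise ConfigurationError(
                "polyorder must satisfy 0 <= polyorder <= window_length - 2")


def savgol_smooth(spectra: np.ndarray, config: SmoothingConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing along the last (band) axis.

    Output shape equals input shape. Edge windows use scipy's ``interp``
    mode (polynomial fit to the boundary window), which reproduces
    polynomials of degree <= ``polyorder`` exactly everywhere.
    """
    config = config or SmoothingConfig()
    spectra = np.asarray(spectra, dtype=float)
    if not config.enabled:
        return spectra.copy()
    if spectra.shape[-1] < config.window_length:
        raise ConfigurationError(
            f"need >= {config.window_length} bands, got {spectra.shape[-1]}"
        )
    return savgol_filter(
        spectra, config.window_length, config.polyorder, axis=-1, mode="interp"
    )


@dataclass(frozen=True)
class Standardizer:
    """Fitted z-score parameters (umol/L), invertible for reporting."""

    mean: float
    sd: float

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize_fit_apply(y: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Fit a z-score on ``y`` (sample SD, ddof=1) and apply it.

    Fit on the training portion only; the returned :class:`Standardizer`
    maps model output back to concentration units.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ConfigurationError("need at least two values to standardize")
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError("constant target: z-score undefined")
    s = Standardizer(mean=float(np.mean(y)), sd=sd)
    return s.apply(y), s


def standardize_invert(z: np.ndarray, s: Standardizer) -> np.ndarray:
    """Map standardized predictions back to concentration units."""
    return s.invert(z)
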