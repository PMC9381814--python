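"""The pipeline's central exchange object: one row per leaf sample.

A :class:`SampleTable` couples each sample's mean leaf reflectance spectrum
with its measured analyte concentrations and minimal metadata (sample id,
experiment of origin). Everything downstream of image segmentation —
smoothing, descriptive statistics, band screening, model fitting — consumes
and produces this object, so it round-trips losslessly through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

_META_COLUMNS = ("sample_id", "experiment")


def wavelength_column(wl: float) -> str:
    """Canonical CSV column name for a band center (nm, 2 decimals)."""
    return f"{wl:.2f}"


@dataclass
class SampleTable:
    """n samples x (metadata, analyte concentrations, mean leaf spectrum).

    Parameters
    ----------
    frame
        Columns ``sample_id``, ``experiment``, one column per analyte
        (concentrations in umol/L), then one column per band named by its
        wavelength in nm (reflectance, dimensionless in [0, 1]).
    analytes
        Names of the analyte columns, in panel order.
    wavelengths
        Band centers in nm, strictly ascending, aligned with the trailing
        spectral columns of ``frame``.
    """

    frame: pd.DataFrame
    analytes: list[str]
    wavelengths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ConfigurationError("wavelengths must be strictly ascending")
        expected = list(_META_COLUMNS) + list(self.analytes) + [
            wavelength_column(w) for w in self.wavelengths
        ]
        missing = [c for c in expected if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"SampleTable frame missing columns: {missing[:5]}")
        # canonical column order
        self.frame = self.frame.loc[:, expected].reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def spectra(self) -> np.ndarray:
        """(n_samples, n_bands) reflectance matrix."""
        cols = [wavelength_column(w) for w in self.wavelengths]
        return self.frame[cols].to_numpy(dtype=float)

    def concentrations(self, analyte: str | None = None):
        """One analyte as a vector, or all analytes as a DataFrame."""
        if analyte is None:
            return self.frame[self.analytes].copy()
        if analyte not in self.analytes:
            raise KeyError(f"unknown analyte {analyte!r}")
        return self.frame[analyte].to_numpy(dtype=float)

    def with_spectra(self, spectra: np.ndarray) -> "SampleTable":
        """Copy of the table with the spectral block replaced (same grid)."""
        spectra = np.asarray(spectra, dtype=float)
        if spectra.shape != (self.n_samples, self.n_bands):
            raise ConfigurationError(
                f"spectra shape {spectra.shape} != {(self.n_samples, self.n_bands)}"
            )
        frame = self.frame.copy()
        frame[[wavelength_column(w) for w in self.wavelengths]] = spectra
        return SampleTable(frame, list(self.analytes), self.wavelengths.copy())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        frame = pd.read_csv(path)
        analytes, wavelengths = [], []
        for col in frame.columns:
            if col in _META_COLUMNS:
                continue
            try:
                wavelengths.append(float(col))
            except ValueError:
                analytes.append(col)
        return cls(frame, analytes, np.asarray(wavelengths, dtype=float))
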