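"""Two-stage sensitive-band screening.

Stage 1 — range partition. The per-band coefficient of variation of
reflectance across samples, CV = SD/mean x 100%, is large in the visible
(pigment-driven) region and small on the NIR plateau; the wavelength axis
is split at a boundary (default 717.08 nm) into a low, variable range and a
high, quiet range, and screening proceeds on the low range.

Stage 2 — coefficient-sorted backward elimination with frequency voting.
On a training split, a PLS model on the candidate bands (component count by
LOO PRESS) yields per-band regression coefficients; bands are sorted by
|coefficient| ascending and removed cumulatively in that fixed order, the
model refit (components re-selected) after each removal and scored by its
minimum LOO PRESS. The surviving subset is the one with the smallest PRESS
along the path. Repeating this over R independent resampled training splits
gives a per-band survival count; bands surviving in more than ``threshold``
of the R repetitions are the analyte's sensitive bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .plsr import fit_pls, press_profile, select_components
from .preprocessing import standardize_fit_apply
from .tables import SampleTable

__all__ = [
    "CVProfile",
    "RangePartition",
    "BandSubsetTrace",
    "FrequencyTable",
    "band_cv_profile",
    "partition_bands",
    "backward_elimination",
    "vote_sensitive_bands",
]


@dataclass
class CVProfile:
    """Per-band reflectance variability across samples."""

    mean: np.ndarray
    sd: np.ndarray
    cv_percent: np.ndarray     # NaN where the band mean is zero

    def finite(self) -> np.ndarray:
        return np.isfinite(self.cv_percent)


@dataclass
class RangePartition:
    """Index split of the wavelength axis at a boundary (nm)."""

    boundary_nm: float
    low_range: np.ndarray      # indices with wavelength <= boundary
    high_range: np.ndarray     # indices with wavelength > boundary


@dataclass
class BandSubsetTrace:
    """One backward-elimination pass.

    ``elimination_order`` lists band indices by ascending |coefficient| in
    the initial fit; step k removes the first k of them. ``surviving_bands``
    is ``elimination_order[best_step:]``.
    """

    elimination_order: np.ndarray
    press_by_step: np.ndarray
    best_step: int
    surviving_bands: np.ndarray


@dataclass
class FrequencyTable:
    """Per-band survival counts over R repetitions and the voted set."""

    band_indices: np.ndarray       # candidate bands (indices into full grid)
    count: np.ndarray              # survival count per candidate band
    R: int
    threshold: int
    wavelengths: np.ndarray | None = field(default=None, repr=False)

    @property
    def sensitive_bands(self) -> np.ndarray:
        """Candidate bands with count strictly above the threshold."""
        return self.band_indices[self.count > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        data = {"band_index": self.band_indices, "count": self.count,
                "selected": self.count > self.threshold}
        if self.wavelengths is not None:
            data = {"wavelength_nm": self.wavelengths[self.band_indices], **data}
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def band_cv_profile(X: np.ndarray, wavelengths: np.ndarray | None = None) -> CVProfile:
    """CV = SD/mean x 100% per band over samples (sample SD, ddof=1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ConfigurationError("CV needs at least two samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0) * 100.0, np.nan)
    return CVProfile(mean=mean, sd=sd, cv_percent=cv)


def partition_bands(wavelengths: np.ndarray, boundary_nm: float = 717.08) -> RangePartition:
    """Split band indices at the boundary; wavelength <= boundary goes low."""
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ConfigurationError("wavelengths must be strictly ascending")
    low = np.flatnonzero(wl <= boundary_nm)
    high = np.flatnonzero(wl > boundary_nm)
    if low.size == 0 or high.size == 0:
        warnings.warn(
            f"boundary {boundary_nm} nm outside the grid: one range is empty",
            stacklevel=2,
        )
    return RangePartition(boundary_nm=boundary_nm, low_range=low, high_range=high)


def backward_elimination(
    X_train: np.ndarray,
    y_train: np.ndarray,
    a_max: int = 15,
    min_bands: int = 2,
    mode: str = "fixed",
) -> BandSubsetTrace:
    """Coefficient-sorted cumulative band removal scored by LOO PRESS.

    ``mode="fixed"`` (default) sorts bands once from the initial
    full-subset fit; ``mode="dynamic"`` re-ranks the remaining bands after
    every removal. Elimination stops when ``min_bands`` bands remain; the
    PRESS recorded at each step is the minimum over admissible component
    counts. Ties in PRESS break toward the larger (earlier) subset.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, b = X.shape
    if b < 2:
        raise ConfigurationError("backward elimination needs at least two bands")
    if not 1 <= min_bands <= b:
        raise ConfigurationError("min_bands must be in 1..n_bands")
    if mode not in ("fixed", "dynamic"):
        raise ConfigurationError(f"unknown elimination mode {mode!r}")

    def _min_press(cols: np.ndarray) -> float:
        return float(press_profile(X[:, cols], y, a_max).min())

    def _coefs(cols: np.ndarray) -> np.ndarray:
        prof = select_components(X[:, cols], y, a_max)
        return fit_pls(X[:, cols], y, prof.a_star).coefficients

    n_steps = b - min_bands + 1
    press_by_step = np.empty(n_steps)

    if mode == "fixed":
        order = np.argsort(np.abs(_coefs(np.arange(b))), kind="stable")
        for k in range(n_steps):
            press_by_step[k] = _min_press(order[k:])
    else:
        order_list: list[int] = []
        remaining = list(range(b))
        for k in range(n_steps):
            cols = np.asarray(remaining)
            press_by_step[k] = _min_press(cols)
            if len(remaining) > min_bands:
                weakest = int(np.argmin(np.abs(_coefs(cols)), ))
                order_list.append(remaining.pop(weakest))
        order = np.asarray(order_list + remaining, dtype=int)

    best_step = int(np.argmin(press_by_step))   # first minimum -> larger subset
    return BandSubsetTrace(
        elimination_order=order,
        press_by_step=press_by_step,
        best_step=best_step,
        surviving_bands=order[best_step:],
    )


def vote_sensitive_bands(
    samples: SampleTable,
    analyte: str,
    candidate_bands: np.ndarray,
    R: int = 100,
    threshold: int = 80,
    train_frac: float = 0.7,
    seed: int = 0,
    a_max: int = 15,
    min_bands: int = 2,
    mode: str = "fixed",
) -> FrequencyTable:
    """Frequency voting over R resampled backward-elimination passes.

    Each repetition draws a fresh training split (``train_frac`` of the
    samples), z-scores the analyte on that split, runs
    :func:`backward_elimination` on the candidate bands, and increments the
    survival count of every surviving band. The voted sensitive set keeps
    bands with count strictly greater than ``threshold``.
    """
    if R < 1:
        raise ConfigurationError("R must be >= 1")
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must be in (0, 1)")
    candidate_bands = np.asarray(candidate_bands, dtype=int)
    if candidate_bands.size < 2:
        raise ConfigurationError("need at least two candidate bands")
    n = samples.n_samples
    n_train = int(round(train_frac * n))
    if n_train < 3 or n - n_train < 1:
        raise ConfigurationError("too few samples for the requested split")

    X_all = samples.spectra()[:, candidate_bands]
    y_all = samples.concentrations(analyte)
    counts = np.zeros(candidate_bands.size, dtype=int)

    for child in np.random.SeedSequence(seed).spawn(R):
        rng = np.random.default_rng(child)
        train = rng.permutation(n)[:n_train]
        z, _ = standardize_fit_apply(y_all[train])
        trace = backward_elimination(X_all[train], z, a_max=a_max,
                                     min_bands=min_bands, mode=mode)
        counts[trace.surviving_bands] += 1

    return FrequencyTable(
        band_indices=candidate_bands,
        count=counts,
        R=R,
        threshold=threshold,
        wavelengths=samples.wavelengths,
    )
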