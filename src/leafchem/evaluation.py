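"""Model evaluation: accuracy metrics, the repeated-holdout harness, and
variant comparison.

Metrics (all on original concentration units, umol/L, over the m test
samples of a repetition):

    R^2  = 1 - sum (y_hat - y)^2 / sum (y - y_bar)^2
    RMSE = sqrt( mean (y - y_hat)^2 )
    RE   = RMSE / y_bar x 100%
    RPD  = SD / RMSE

with y_bar and SD the test-set mean and sample SD of the measured values.
RPD > 2 conventionally marks a usable calibration.

The harness repeats a 70/30 holdout R times (train size = round(0.7 n), so
290 samples split 203/87): per repetition the analyte is z-scored on the
training portion, the PLS component count is re-selected by LOO PRESS on
that training set, the model is fit and applied to the test spectra, and
predictions are mapped back to umol/L before metrics. Averages over the R
repetitions summarize accuracy and stability. Variant comparison (all
bands / low range / high range / voted sensitive bands) shares one split
sequence across variants so the comparison is paired; the winner is the
variant with the highest mean R^2 (ties: higher mean RPD, then fewer bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .plsr import fit_pls, select_components
from .preprocessing import standardize_fit_apply
from .tables import SampleTable

__all__ = [
    "MetricSet",
    "HoldoutResult",
    "EvaluationSummary",
    "OptimalChoice",
    "compute_metrics",
    "repeated_holdout",
    "compare_variants",
    "descriptive_stats",
]

_METRICS = ("r2", "rmse", "re", "rpd")


@dataclass(frozen=True)
class MetricSet:
    """One repetition's test-set accuracy."""

    r2: float
    rmse: float
    re: float
    rpd: float
    m: int
    y_mean: float
    y_sd: float


@dataclass
class HoldoutResult:
    """Per-repetition metric records plus their arithmetic means."""

    records: pd.DataFrame          # columns: rep, a_star, r2, rmse, re, rpd
    means: dict

    @property
    def a_star_counts(self) -> pd.Series:
        return self.records["a_star"].value_counts().sort_index()


@dataclass
class EvaluationSummary:
    """Mean metrics per band-set variant (paired over one split sequence)."""

    analyte: str
    per_variant: dict = field(default_factory=dict)   # label -> HoldoutResult
    n_bands: dict = field(default_factory=dict)       # label -> band count

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for label, res in self.per_variant.items():
            rows.append({"variant": label, "n_bands": self.n_bands[label],
                         **{k: res.means[k] for k in _METRICS}})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OptimalChoice:
    """Winning band-set variant for one analyte."""

    analyte: str
    variant: str
    means: dict
    n_bands: int


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """Test-set metrics in the units of ``y_true`` (umol/L).

    Perfect prediction yields (R^2 = 1, RMSE = 0, RE = 0, RPD = inf); the
    test-mean predictor yields R^2 exactly 0.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ConfigurationError("y_true and y_pred lengths differ")
    m = y_true.size
    if m < 2:
        raise ConfigurationError("need at least two test samples")
    y_bar = float(np.mean(y_true))
    if y_bar == 0.0:
        raise ConfigurationError("zero test mean: RE undefined")
    sd = float(np.std(y_true, ddof=1))
    sse = float(np.sum((y_pred - y_true) ** 2))
    sst = float(np.sum((y_true - y_bar) ** 2))
    rmse = float(np.sqrt(sse / m))
    return MetricSet(
        r2=1.0 - sse / sst if sst > 0 else np.nan,
        rmse=rmse,
        re=rmse / y_bar * 100.0,
        rpd=sd / rmse if rmse > 0 else np.inf,
        m=m,
        y_mean=y_bar,
        y_sd=sd,
    )


def _make_splits(n: int, train_frac: float, R: int, seed: int,
                 strata: np.ndarray | None = None) -> list:
    """R (train, test) index pairs; optionally stratified by a label array."""
    n_train = int(round(train_frac * n))
    if n_train < 3 or n - n_train < 2:
        raise ConfigurationError("too few samples for the requested split")
    splits = []
    for child in np.random.SeedSequence(seed).spawn(R):
        rng = np.random.default_rng(child)
        if strata is None:
            perm = rng.permutation(n)
            splits.append((perm[:n_train], perm[n_train:]))
        else:
            train_parts = []
            for s in np.unique(strata):
                idx = np.flatnonzero(strata == s)
                k = int(round(train_frac * idx.size))
                train_parts.append(rng.permutation(idx)[:k])
            train = np.concatenate(train_parts)
            test = np.setdiff1d(np.arange(n), train)
            splits.append((train, test))
    return splits


def _holdout_over_splits(X: np.ndarray, y: np.ndarray, splits: list,
                         a_max: int) -> HoldoutResult:
    rows = []
    for rep, (train, test) in enumerate(splits):
        z, scaler = standardize_fit_apply(y[train])
        a_star = select_components(X[train], z, a_max).a_star
        model = fit_pls(X[train], z, a_star)
        pred = scaler.invert(model.predict(X[test]))
        ms = compute_metrics(y[test], pred)
        rows.append({"rep": rep, "n_train": train.size, "m_test": ms.m,
                     "a_star": a_star, **{k: getattr(ms, k) for k in _METRICS}})
    records = pd.DataFrame(rows)
    means = {k: float(records[k].mean()) for k in _METRICS}
    return HoldoutResult(records=records, means=means)


def repeated_holdout(
    samples: SampleTable,
    analyte: str,
    band_set: np.ndarray | None = None,
    R: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    a_max: int = 15,
    stratify_by_experiment: bool = False,
) -> HoldoutResult:
    """R-fold repeated random holdout for one analyte on one band set.

    ``band_set=None`` uses all bands. Component count is re-selected by LOO
    PRESS inside every repetition; metrics are computed on original units.
    """
    X = samples.spectra()
    if band_set is not None:
        X = X[:, np.asarray(band_set, dtype=int)]
    y = samples.concentrations(analyte)
    strata = (samples.frame["experiment"].to_numpy()
              if stratify_by_experiment else None)
    splits = _make_splits(samples.n_samples, train_frac, R, seed, strata)
    return _holdout_over_splits(X, y, splits, a_max)


def compare_variants(
    samples: SampleTable,
    analyte: str,
    variants: dict,
    R: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    a_max: int = 15,
    stratify_by_experiment: bool = False,
) -> tuple[EvaluationSummary, OptimalChoice]:
    """Paired comparison of band-set variants for one analyte.

    ``variants`` maps label -> band index array (or None for all bands).
    All variants see the identical split sequence. The winner maximizes
    mean R^2; ties break by higher mean RPD, then fewer bands, then variant
    order.
    """
    if len(variants) < 2:
        raise ConfigurationError("need at least two variants to compare")
    X_full = samples.spectra()
    y = samples.concentrations(analyte)
    strata = (samples.frame["experiment"].to_numpy()
              if stratify_by_experiment else None)
    splits = _make_splits(samples.n_samples, train_frac, R, seed, strata)

    summary = EvaluationSummary(analyte=analyte)
    for label, band_set in variants.items():
        X = X_full if band_set is None else X_full[:, np.asarray(band_set, dtype=int)]
        summary.per_variant[label] = _holdout_over_splits(X, y, splits, a_max)
        summary.n_bands[label] = X.shape[1]

    def _rank(item):
        label, res = item
        return (-res.means["r2"], -res.means["rpd"], summary.n_bands[label])

    best_label, best = min(summary.per_variant.items(), key=_rank)
    choice = OptimalChoice(analyte=analyte, variant=best_label,
                           means=dict(best.means), n_bands=summary.n_bands[best_label])
    return summary, choice


def descriptive_stats(samples: SampleTable, analyte: str | None = None) -> pd.DataFrame:
    """Max/min/mean/SD/CV% per analyte (sample SD, CV = SD/mean x 100)."""
    names = samples.analytes if analyte is None else [analyte]
    rows = []
    for name in names:
        y = samples.concentrations(name)
        if y.size < 2:
            raise ConfigurationError("descriptives need at least two samples")
        mean = float(np.mean(y))
        sd = float(np.std(y, ddof=1))
        rows.append({
            "analyte": name, "max": float(np.max(y)), "min": float(np.min(y)),
            "mean": mean, "sd": sd,
            "cv_percent": sd / mean * 100.0 if mean != 0 else np.nan,
        })
    return pd.DataFrame(rows)
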