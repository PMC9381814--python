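"""NIPALS partial least squares regression for a single response.

PLS1 in the classic Wold formulation: components are extracted one at a
time, each weight vector proportional to the cross-covariance between the
(deflated) predictors and the response, with X-deflation between
components. Predictors are mean-centered internally but never
variance-scaled — reflectance shares units across bands — while the
response is expected already z-scored by the preprocessing module.

Model-order selection follows the predicted residual error sum of squares
(PRESS): for each candidate component count A the leave-one-out
cross-validation error is accumulated from n honest refits, and the
smallest A attaining the minimum PRESS is kept. The refits are genuine —
no virtual-leverage shortcut — so the LOO oracle property (equality with an
explicit fit/predict loop) holds by construction and is asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import RankError, ZeroVarianceError

__all__ = ["PLSModel", "PressProfile", "fit_pls", "predict_pls", "loo_press",
           "select_components", "press_profile"]

_EPS = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 state sufficient for prediction on new spectra.

    ``coefficients`` is the per-band regression vector for the fitted
    component count (standardized-response units per reflectance unit);
    ``coef_path[:, a-1]`` gives the coefficient vector truncated to ``a``
    components, exploiting the nestedness of NIPALS components.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray            # bands x A, unit-norm columns
    x_loadings: np.ndarray         # bands x A
    y_loadings: np.ndarray         # A
    coefficients: np.ndarray       # bands
    coef_path: np.ndarray = field(repr=False, default=None)
    band_indices: np.ndarray | None = None
    y_sd: float = 1.0

    def predict(self, X_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"band count {X_new.shape[1]} != model's {self.x_mean.size}"
            )
        if n_components is None:
            beta = self.coefficients
        else:
            if not 1 <= n_components <= self.coef_path.shape[1]:
                raise RankError(f"n_components must be in 1..{self.coef_path.shape[1]}")
            beta = self.coef_path[:, n_components - 1]
        return (X_new - self.x_mean) @ beta + self.y_mean


@dataclass
class PressProfile:
    """LOO PRESS per candidate component count 1..A_max and its argmin."""

    press: np.ndarray
    a_star: int

    def __post_init__(self):
        if np.any(self.press < 0) or not 1 <= self.a_star <= self.press.size:
            raise ValueError("inconsistent PRESS profile")


def _nipals(Xc: np.ndarray, yc: np.ndarray, A: int):
    """Core NIPALS loop on centered data; returns (W, P, q, coef_path, a_eff).

    Stops early if the residual cross-covariance or score norm vanishes
    (rank exhausted); coefficient columns beyond that repeat the last value
    so downstream indexing by component count stays valid.
    """
    n, b = Xc.shape
    W = np.zeros((b, A))
    P = np.zeros((b, A))
    q = np.zeros(A)
    R = np.zeros((b, A))           # W (P'W)^{-1}, built by recursion
    coef_path = np.zeros((b, A))
    X = Xc.copy()
    beta = np.zeros(b)
    a_eff = 0
    for a in range(A):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw <= _EPS:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p = (X.T @ t) / tt
        qa = float(yc @ t) / tt
        X -= np.outer(t, p)
        W[:, a] = w
        P[:, a] = p
        q[a] = qa
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        R[:, a] = r
        beta = beta + qa * r
        coef_path[:, a] = beta
        a_eff += 1
    for a in range(a_eff, A):      # rank exhausted: freeze the coefficient
        coef_path[:, a] = coef_path[:, a_eff - 1] if a_eff > 0 else 0.0
    return W, P, q, coef_path, a_eff


def fit_pls(X: np.ndarray, y: np.ndarray, A: int,
            band_indices: np.ndarray | None = None) -> PLSModel:
    """Fit a PLS1 model with ``A`` components.

    ``X`` is n x bands reflectance; ``y`` the (standardized) response.
    ``A`` must not exceed min(n - 1, bands).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, b = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if n < 2:
        raise ValueError("need at least two samples")
    if not 1 <= A <= min(n - 1, b):
        raise RankError(f"A={A} exceeds min(n-1, bands)={min(n - 1, b)}")
    if np.std(y) <= _EPS:
        raise ZeroVarianceError("constant response: PLS undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, coef_path, a_eff = _nipals(X - x_mean, y - y_mean, A)
    a_use = max(a_eff, 1)
    return PLSModel(
        n_components=a_use,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:, :a_use],
        x_loadings=P[:, :a_use],
        y_loadings=q[:a_use],
        coefficients=coef_path[:, A - 1].copy(),
        coef_path=coef_path,
        band_indices=None if band_indices is None else np.asarray(band_indices),
    )


def predict_pls(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict (standardized-unit) responses for new spectra."""
    return model.predict(X_new)


def press_profile(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """LOO PRESS for every component count 1..min(a_max, n-2, bands).

    One NIPALS fit per left-out sample; predictions for all candidate
    component counts are read off the nested coefficient path of that fit,
    which is arithmetically identical to refitting per count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, b = X.shape
    if n < 3:
        raise ValueError("LOO needs at least three samples")
    a_cap = min(a_max, n - 2, b)
    if a_cap < 1:
        raise RankError("no admissible component count")
    sq = np.zeros(a_cap)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xd, yd = X[keep], y[keep]
        x_mean = Xd.mean(axis=0)
        y_mean = yd.mean()
        _, _, _, coef_path, _ = _nipals(Xd - x_mean, yd - y_mean, a_cap)
        preds = (X[i] - x_mean) @ coef_path + y_mean
        sq += (y[i] - preds) ** 2
    return sq


def loo_press(X: np.ndarray, y: np.ndarray, A: int) -> float:
    """Leave-one-out PRESS at component count ``A``.

    Per fold the component count is capped at min(n - 2, bands); the value
    equals a brute-force loop of n independent ``fit_pls``/``predict`` calls.
    """
    return float(press_profile(X, y, A)[-1])


def select_components(X: np.ndarray, y: np.ndarray, a_max: int = 15) -> PressProfile:
    """PRESS profile over 1..A_max and the most parsimonious minimizer.

    Ties (exact PRESS equality) break toward the smallest component count.
    """
    if a_max < 1:
        raise RankError("a_max must be >= 1")
    press = press_profile(X, y, a_max)
    return PressProfile(press=press, a_star=int(np.argmin(press)) + 1)
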