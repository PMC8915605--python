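"""Weighted regression and the shared prediction-quality metric suite.

Solubility measurements are heteroscedastic: each log S0 entry carries an
estimated measurement SD.  All model fits therefore use inverse-variance
weights w_i = 1 / max(sd_i, sd_floor)^2, with a floor that keeps a single
ultra-precise entry from dominating the fit.

Two fitters are provided:

* :func:`weighted_mlr` — weighted multiple linear regression (via
  statsmodels WLS), the workhorse for the GSE and ABSOLV linear fits;
* :func:`pls_fit` — PLS1 regression on the weighted data, used where the
  descriptors are strongly collinear (the nonlinear-basicity exponent scan).
  The PLS core is an uncentered NIPALS run on weighted-centered,
  sqrt(weight)-scaled data, so that with the full number of components on a
  full-rank design it reproduces weighted MLR exactly; off-the-shelf PLS
  implementations center unweighted and cannot honour the measurement
  weights.

The metric suite matches the field's reporting conventions: RMSE, r^2
(floored at 0 for predictions worse than the mean), bias (mean residual),
SD of the observations, the F statistic, and MPP — the percentage of
predictions within 0.5 log unit of the measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from sklearn.model_selection import KFold

from .errors import ConfigurationError, SingularDesignError, ValidationError

SD_FLOOR = 0.05
"""Default lower bound (log units) on measurement SDs used for weighting."""

DEFAULT_THRESHOLD = 0.5
"""Residual threshold (log units) defining a 'correct' prediction for MPP."""


@dataclass(frozen=True)
class MetricsReport:
    """Prediction-quality metrics for one (observed, calculated) set."""

    n: int
    rmse: float
    r2: float
    bias: float
    sd: float
    mpp: float
    f_stat: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse": round(self.rmse, 2),
            "r2": round(self.r2, 2),
            "bias": round(self.bias, 2),
            "sd": round(self.sd, 2),
            "mpp": int(round(self.mpp)),
            "f_stat": None if self.f_stat is None else round(self.f_stat, 2),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class WeightedFit:
    """Result of a weighted regression."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    weights_used: np.ndarray
    method: str  # "MLR" | "PLS"
    pls_components: int | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.standard_errors):
            raise ValidationError("coefficient and SE vectors must have equal length")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict for a design matrix laid out as the one used in fitting."""
        return np.asarray(X, dtype=float) @ self.coefficients


def _weights(sd: np.ndarray, sd_floor: float) -> np.ndarray:
    sd = np.asarray(sd, dtype=float)
    return 1.0 / np.maximum(sd, sd_floor) ** 2


def _check_rank(X: np.ndarray) -> None:
    """Raise SingularDesignError naming (near-)dependent columns."""
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal does not lower the rank
        dependent = [
            j for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise SingularDesignError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} columns); "
            f"dependent column indices: {dependent}"
        )


def weighted_mlr(
    X: np.ndarray,
    y: np.ndarray,
    sd: np.ndarray | None = None,
    *,
    sd_floor: float = SD_FLOOR,
) -> WeightedFit:
    """Inverse-variance weighted multiple linear regression.

    ``X`` is the full design matrix including any intercept column.  ``sd``
    gives per-observation measurement SDs; ``None`` means equal weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("X must be 2-D with one row per observation")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError(
            f"need more observations ({X.shape[0]}) than parameters ({X.shape[1]})"
        )
    w = np.ones(len(y)) if sd is None else _weights(sd, sd_floor)
    if len(w) != len(y):
        raise ValidationError("sd vector length must match y")
    _check_rank(X)
    res = sm.WLS(y, X, weights=w).fit()
    return WeightedFit(
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        weights_used=w,
        method="MLR",
    )


# ---------------------------------------------------------------------------
# PLS1 (NIPALS without internal centering)
# ---------------------------------------------------------------------------

def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """PLS1 regression coefficients on already-prepared (centered/scaled) data.

    No internal centering: callers hand in weighted-centered and
    sqrt(weight)-scaled matrices.  With n_components equal to the rank of X
    the result coincides with the least-squares solution.
    """
    X = X.copy()
    y = y.copy().astype(float)
    n, p = X.shape
    W = np.zeros((p, n_components))  # X weights
    P = np.zeros((p, n_components))  # X loadings
    q = np.zeros(n_components)       # y loadings
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-28:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        p_load = (X.T @ t) / tt
        q_load = (y @ t) / tt
        X -= np.outer(t, p_load)
        y -= q_load * t
        W[:, a], P[:, a], q[a] = w, p_load, q_load
    if W.shape[1] == 0:
        return np.zeros(p)
    # beta = W (P^T W)^{-1} q
    return W @ np.linalg.solve(P.T @ W, q)


def _prepare_weighted(X, y, w):
    """Weighted-center X and y, scale rows by sqrt(w); return pieces to undo."""
    sw = np.sqrt(w)
    xbar = np.average(X, axis=0, weights=w)
    ybar = np.average(y, weights=w)
    Xc = (X - xbar) * sw[:, None]
    yc = (y - ybar) * sw
    return Xc, yc, xbar, ybar


def select_pls_components(
    X: np.ndarray,
    y: np.ndarray,
    sd: np.ndarray | None = None,
    *,
    max_components: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
    sd_floor: float = SD_FLOOR,
) -> int:
    """Pick the PLS component count by 10-fold cross-validated RMSE.

    Ties (exact equal CV RMSE) break toward fewer components; the fold
    assignment is a fixed shuffle from ``seed`` so the choice is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if sd is None else _weights(sd, sd_floor)
    kmax = max_components or X.shape[1]
    folds = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    press = np.zeros(kmax)
    for train, test in folds.split(X):
        Xc, yc, xbar, ybar = _prepare_weighted(X[train], y[train], w[train])
        for k in range(1, kmax + 1):
            beta = _nipals_pls1(Xc, yc, k)
            pred = (X[test] - xbar) @ beta + ybar
            press[k - 1] += np.sum(w[test] * (y[test] - pred) ** 2)
    return int(np.argmin(press)) + 1  # argmin returns the first (fewest) minimum


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    sd: np.ndarray | None = None,
    n_components: int | None = None,
    *,
    sd_floor: float = SD_FLOOR,
    seed: int = 0,
) -> WeightedFit:
    """PLS1 regression on SD-weighted data.

    ``X`` must not contain an intercept column; the intercept is recovered
    from the weighted means and returned as coefficient 0, so the
    coefficient vector is directly comparable to
    ``weighted_mlr([1 | X], y, sd)``.  ``n_components=None`` selects the
    count by seeded 10-fold cross-validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("X must be 2-D with one row per observation")
    p = X.shape[1]
    if n_components is None:
        n_components = select_pls_components(X, y, sd, seed=seed, sd_floor=sd_floor)
    if not (1 <= n_components <= p):
        raise ConfigurationError(f"n_components must be in [1, {p}], got {n_components}")
    w = np.ones(len(y)) if sd is None else _weights(sd, sd_floor)
    Xc, yc, xbar, ybar = _prepare_weighted(X, y, w)
    beta = _nipals_pls1(Xc, yc, n_components)
    coeffs = np.concatenate([[ybar - xbar @ beta], beta])
    return WeightedFit(
        coefficients=coeffs,
        standard_errors=np.full(p + 1, np.nan),  # PLS has no closed-form SEs
        weights_used=w,
        method="PLS",
        pls_components=n_components,
    )


# ---------------------------------------------------------------------------
# Metric suite
# ---------------------------------------------------------------------------

def evaluate(
    obs: np.ndarray,
    pred: np.ndarray,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    n_params: int | None = None,
) -> MetricsReport:
    """Compute RMSE, floored r^2, bias, SD, MPP and (optionally) F.

    Residuals are observed minus calculated.  r^2 = max(0, 1 - SSres/SStot):
    a model predicting worse than the observation mean reports 0.  The F
    statistic needs the number of regression parameters ``n_params`` (p in
    F = (n-p-1)/p * SStot/SSres) and is omitted when not given.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 1:
        raise ValidationError("obs and pred must be equal-length 1-D vectors")
    resid = obs - pred
    n = len(obs)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    bias = float(np.mean(resid))
    sd = float(np.sqrt(np.mean((obs - obs.mean()) ** 2)))
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    mpp = float(100.0 * np.mean(np.abs(resid) <= threshold))
    f_stat = None
    if n_params is not None and ss_res > 0:
        f_stat = float((n - n_params - 1) / n_params * ss_tot / ss_res)
    return MetricsReport(n=n, rmse=rmse, r2=r2, bias=bias, sd=sd, mpp=mpp, f_stat=f_stat)
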