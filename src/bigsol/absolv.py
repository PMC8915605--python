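"""Abraham solvation (ABSOLV) solubility model and its extensions.

The linear model predicts intrinsic solubility from the five Abraham solute
descriptors plus the acid-base cross term:

    log S0 = c0 + cA*A + cB*B + cS*S_pi + cE*E + cV*V + cAB*A*B

Two extensions target big (MW >= 800 Da) molecules:

* a nonlinear basicity term cBz * B**z, with the exponent z chosen by
  scanning [0.9, 2.0] for the minimum PLS RMSE (big molecules carry
  unusually high H-bond basicity, and amplifying B improves the fit);
* a rotatable-bond residual correction: the small-molecule-trained model
  underpredicts big-molecule solubility by an amount that grows roughly
  linearly with nROT, so adding ``intercept + slope * nROT`` to the
  prediction removes most of the systematic bias.  Flexibility, crudely
  indexed by nROT, is what the small-molecule training set fails to carry
  over to big molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import AbrahamDescriptors, CompoundRecord, SolubilityEntry
from .errors import ConfigurationError, SingularDesignError, ValidationError
from .regression import (
    SD_FLOOR, MetricsReport, WeightedFit, evaluate, pls_fit,
    select_pls_components, weighted_mlr,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbsolvCoefficients:
    """Coefficients of the (optionally extended) Abraham solubility model."""

    c0: float
    c_A: float
    c_B: float
    c_S: float
    c_E: float
    c_V: float
    c_AB: float
    c_Bz: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if (self.c_Bz is None) != (self.z is None):
            raise ValidationError("c_Bz and z must be provided together")
        if self.z is not None and self.z <= 0:
            raise ValidationError(f"exponent z must be > 0, got {self.z}")

    def as_array(self) -> np.ndarray:
        base = [self.c0, self.c_A, self.c_B, self.c_S, self.c_E, self.c_V, self.c_AB]
        if self.c_Bz is not None:
            base.append(self.c_Bz)
        return np.array(base)


ABSOLV_2020 = AbsolvCoefficients(
    c0=-0.017925, c_A=0.199827, c_B=1.78374, c_S=-0.108478,
    c_E=-1.168789, c_V=-1.492908, c_AB=0.008288,
)
"""Small-molecule-trained ABSOLV coefficient preset.

Reconstructed by over-determined least squares from the packaged
big-molecule reference table (31 ABSOLV predictions against the 31
descriptor rows, 7 unknowns); the reconstruction reproduces every reference
prediction to better than 0.005 log.  As expected, the A*B cross-term
coefficient is negligible.
"""

PRESETS = {"absolv-2020": ABSOLV_2020}

_DESCRIPTOR_FIELDS = ("A", "B", "S_pi", "E", "V")


def predict_absolv(desc: AbrahamDescriptors, coeffs: AbsolvCoefficients = ABSOLV_2020) -> float:
    """Predict log S0 (log molar) from Abraham descriptors."""
    if desc is None:
        raise ValidationError("missing Abraham descriptors")
    for fname in _DESCRIPTOR_FIELDS:
        v = getattr(desc, fname)
        if v is None or not np.isfinite(v):
            raise ValidationError(f"missing Abraham descriptor {fname!r}")
    value = (
        coeffs.c0
        + coeffs.c_A * desc.A
        + coeffs.c_B * desc.B
        + coeffs.c_S * desc.S_pi
        + coeffs.c_E * desc.E
        + coeffs.c_V * desc.V
        + coeffs.c_AB * desc.AB
    )
    if coeffs.c_Bz is not None:
        value += coeffs.c_Bz * desc.B_pow(coeffs.z)
    return float(value)


def _design(pairs, z: float | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = [(r, e) for r, e in pairs if r.abraham is not None]
    if not rows:
        raise ValidationError("no compounds with Abraham descriptors")
    X = np.array([
        [r.abraham.A, r.abraham.B, r.abraham.S_pi, r.abraham.E, r.abraham.V, r.abraham.AB]
        + ([r.abraham.B_pow(z)] if z is not None else [])
        for r, _ in rows
    ])
    y = np.array([e.log_s0 for _, e in rows])
    sd = np.array([e.sd if e.sd is not None else SD_FLOOR for _, e in rows])
    return X, y, sd


def fit_absolv(
    pairs: Sequence[tuple[CompoundRecord, SolubilityEntry]],
    *,
    sd_floor: float = SD_FLOOR,
) -> tuple[AbsolvCoefficients, WeightedFit, MetricsReport]:
    """SD-weighted MLR of log S0 on (1, A, B, S_pi, E, V, A*B)."""
    X, y, sd = _design(pairs)
    if len(y) < 9:
        raise ValidationError(f"need >= 9 compounds with descriptors, got {len(y)}")
    X1 = np.column_stack([np.ones(len(y)), X])
    names = ["c0", "c_A", "c_B", "c_S", "c_E", "c_V", "c_AB"]
    try:
        fit = weighted_mlr(X1, y, sd, sd_floor=sd_floor)
    except SingularDesignError as exc:
        # translate column indices into coefficient names
        degenerate = [names[j] for j in range(7) if np.ptp(X1[:, j]) == 0 and j > 0]
        raise SingularDesignError(
            f"inestimable coefficient(s) {degenerate or 'unknown'}: {exc}"
        ) from exc
    coeffs = AbsolvCoefficients(*fit.coefficients)
    metrics = evaluate(y, fit.predict(X1), n_params=6)
    return coeffs, fit, metrics


def z_scan(
    pairs: Sequence[tuple[CompoundRecord, SolubilityEntry]],
    z_grid: np.ndarray | None = None,
    *,
    weighted: bool = True,
    seed: int = 0,
    sd_floor: float = SD_FLOOR,
) -> tuple[float, pd.DataFrame]:
    """Scan the nonlinear basicity exponent z for minimum PLS RMSE.

    For each z on the grid (default 0.90 to 2.00 in steps of 0.01) the design
    (A, B, S_pi, E, V, A*B, B**z) is fitted by SD-weighted PLS with the
    component count chosen by seeded cross-validation, and the training RMSE
    recorded.  Returns the argmin z (ties toward smaller z) and the full scan
    table (z, rmse, components).  Set ``weighted=False`` to drop the
    measurement-SD weighting.
    """
    if z_grid is None:
        z_grid = np.arange(90, 201) / 100.0
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.size == 0:
        raise ConfigurationError("z grid is empty")
    rows = [(r, e) for r, e in pairs if r.abraham is not None]
    if any(r.abraham.B <= 0 for r, _ in rows):
        raise ValidationError("z scan requires B > 0 for all compounds")
    records = []
    for z in z_grid:
        X, y, sd = _design(rows, z=float(z))
        sd_arg = sd if weighted else None
        k = select_pls_components(X, y, sd_arg, seed=seed, sd_floor=sd_floor)
        fit = pls_fit(X, y, sd_arg, n_components=k, sd_floor=sd_floor)
        pred = fit.coefficients[0] + X @ fit.coefficients[1:]
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        records.append({"z": float(z), "rmse": rmse, "components": k})
    table = pd.DataFrame(records)
    z_best = float(table.loc[table.rmse.idxmin(), "z"])  # idxmin -> first = smallest z
    return z_best, table


@dataclass(frozen=True)
class NrotCorrection:
    """Additive rotatable-bond correction for big-molecule predictions."""

    intercept: float
    slope: float

    def apply(self, prediction: float, nrot: int) -> float:
        if nrot is None:
            raise ValidationError("nROT correction requires a rotatable-bond count")
        return prediction + self.intercept + self.slope * nrot


def fit_nrot_correction(
    records: Sequence[CompoundRecord],
    obs: np.ndarray,
    absolv_pred: np.ndarray,
) -> tuple[NrotCorrection, WeightedFit, MetricsReport]:
    """Unweighted OLS of the residual (obs - ABSOLV) on nROT.

    The regression is run over compounds with an nROT count (intended for
    the big set).  The returned metrics describe the residual-vs-nROT line
    itself (its r^2 is the share of systematic error explained by
    flexibility).
    """
    keep = [i for i, r in enumerate(records) if r.nrot is not None]
    if len(keep) < 3:
        raise ValidationError(f"need >= 3 compounds with nROT, got {len(keep)}")
    nrot = np.array([records[i].nrot for i in keep], dtype=float)
    if np.ptp(nrot) == 0:
        raise SingularDesignError("all nROT values are equal; slope is inestimable")
    resid = np.asarray(obs, dtype=float)[keep] - np.asarray(absolv_pred, dtype=float)[keep]
    X = np.column_stack([np.ones(len(keep)), nrot])
    fit = weighted_mlr(X, resid, None)
    corr = NrotCorrection(intercept=float(fit.coefficients[0]), slope=float(fit.coefficients[1]))
    metrics = evaluate(resid, fit.predict(X), n_params=1)
    return corr, fit, metrics


def apply_nrot_correction(
    correction: NrotCorrection,
    records: Sequence[CompoundRecord],
    absolv_pred: np.ndarray,
) -> np.ndarray:
    """Apply the correction element-wise: prediction + a + b * nROT."""
    return np.array([
        correction.apply(p, r.nrot) for r, p in zip(records, np.asarray(absolv_pred, dtype=float))
    ])
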