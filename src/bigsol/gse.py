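"""General Solubility Equation (GSE) and its retrained big-molecule variant.

The classic GSE predicts intrinsic aqueous solubility (log10 molar) from two
inputs only:

    log S0 = 0.5 - 0.01 (mp - 25) - log P

where mp is the melting point in deg C and log P the octanol-water partition
coefficient.  The melting-point term comes from the crystal-lattice
contribution under Walden's rule (entropy of melting ~0.0565 kJ/mol/K,
2.3RT = 5.706 kJ/mol at 25 deg C); the log P term models solvation of the
supercooled liquid.

For big molecules (MW >= 800 Da) the same functional form holds but the
SD-weighted refit gives a much shallower lipophilicity slope and a lower
intercept; the `gse-big-2020` preset carries those constants
(-1.77, -0.01, -0.4).  The two lines cross near clogP ~ 3.8: the classic GSE
overpredicts big-molecule solubility on the hydrophilic side of the
crossover and underpredicts on the lipophilic side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import CompoundRecord, SolubilityEntry
from .errors import NoCrossoverError, ValidationError
from .regression import SD_FLOOR, MetricsReport, WeightedFit, evaluate, weighted_mlr

logger = logging.getLogger(__name__)

#: Walden's-rule entropy of melting, kJ/(mol K) — documents the derivation of
#: the -0.01/deg C melting-point coefficient.
WALDEN_DS_MELT = 0.0565
#: 2.3 RT at 25 deg C, kJ/mol.
RT_LN10_25C = 5.706


@dataclass(frozen=True)
class GseCoefficients:
    """Coefficients of a GSE-form line log S0 = a + b (mp - 25) + c logP."""

    intercept: float
    mp_coef: float
    logp_coef: float
    provenance: str = "fitted"  # "classic" | "fitted"

    def __post_init__(self) -> None:
        if self.provenance == "classic" and (self.intercept, self.mp_coef, self.logp_coef) != (
            0.5, -0.01, -1.0,
        ):
            raise ValidationError("classic provenance requires coefficients (0.5, -0.01, -1)")


GSE_CLASSIC = GseCoefficients(0.5, -0.01, -1.0, provenance="classic")
"""The untrained textbook GSE."""

GSE_BIG_2020 = GseCoefficients(-1.77, -0.01, -0.4, provenance="fitted")
"""SD-weighted refit on big molecules (MW >= 800 Da): shallow -0.4
lipophilicity slope, -1.77 intercept; the melting-point coefficient stays at
the classic -0.01/deg C."""

PRESETS = {"gse-classic": GSE_CLASSIC, "gse-big-2020": GSE_BIG_2020}


def predict_gse(mp: float, logp: float, coeffs: GseCoefficients = GSE_CLASSIC) -> float:
    """Predict log S0 (log molar) from melting point (deg C) and log P."""
    if not (math.isfinite(mp) and math.isfinite(logp)):
        raise ValidationError(f"mp and logp must be finite, got mp={mp}, logp={logp}")
    if mp < 25:
        logger.warning(
            "mp = %.1f degC is below 25 degC; the solid-phase premise of the "
            "melting-point term weakens", mp,
        )
    return coeffs.intercept + coeffs.mp_coef * (mp - 25.0) + coeffs.logp_coef * logp


def fit_gse(
    pairs: Sequence[tuple[CompoundRecord, SolubilityEntry]],
    *,
    sd_floor: float = SD_FLOOR,
) -> tuple[GseCoefficients, WeightedFit, MetricsReport]:
    """SD-weighted MLR of log S0 on (1, mp - 25, clogP).

    Returns the fitted coefficients, the full regression result (with
    standard errors) and training metrics.
    """
    rows = [(r, e) for r, e in pairs if r.mp is not None and r.clogp is not None]
    if len(rows) < 4:
        raise ValidationError(f"need >= 4 compounds with mp, clogP and log S0; got {len(rows)}")
    X = np.array([[1.0, r.mp - 25.0, r.clogp] for r, _ in rows])
    y = np.array([e.log_s0 for _, e in rows])
    sd = np.array([e.sd if e.sd is not None else np.nan for _, e in rows])
    sd = np.where(np.isnan(sd), sd_floor, sd)
    fit = weighted_mlr(X, y, sd, sd_floor=sd_floor)
    coeffs = GseCoefficients(*fit.coefficients, provenance="fitted")
    metrics = evaluate(y, fit.predict(X), n_params=2)
    return coeffs, fit, metrics


def gse_crossover(
    coeffs_a: GseCoefficients,
    coeffs_b: GseCoefficients,
    mp: float = 25.0,
) -> tuple[float, float]:
    """log P and log S0 at which two GSE lines predict equally, at fixed mp.

    Raises :class:`NoCrossoverError` when the lipophilicity slopes are equal
    (parallel lines, or the identical line).
    """
    dslope = coeffs_a.logp_coef - coeffs_b.logp_coef
    if dslope == 0:
        raise NoCrossoverError("the two GSE lines have equal logP slopes and never cross")
    dconst = (coeffs_b.intercept - coeffs_a.intercept) + (
        coeffs_b.mp_coef - coeffs_a.mp_coef
    ) * (mp - 25.0)
    logp = dconst / dslope
    return logp, predict_gse(mp, logp, coeffs_a)
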