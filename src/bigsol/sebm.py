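"""Solubility Enhancement-Big Molecules (SEBM) index and GSE zoning.

SEBM is the ratio of the observed intrinsic solubility to the value the
small-molecule-trained Abraham model predicts:

    SEBM = S0_obs / S0_absolv = 10 ** (log S0_obs - log S0_absolv)

For the big-molecule set the ratio is >= 1 essentially everywhere — the
small-molecule model underpredicts big-molecule solubility, by as much as
ten orders of magnitude (gramicidin A).  In published tables the ratio is
printed as an integer (half-away-from-zero; sub-unity ratios print as 1);
full precision is kept internally.

A companion zoning uses the classic GSE instead: a compound whose observed
solubility exceeds the GSE prediction sits in the 'enhancement' zone, below
it in the 'attenuation' zone.  The GSE zoning tracks lipophilicity, whereas
SEBM assigns a unified enhancement driven by H-bonding and size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .absolv import NrotCorrection, fit_nrot_correction
from .datasets import CompoundRecord
from .errors import ValidationError
from .regression import MetricsReport, WeightedFit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SebmRecord:
    """SEBM enhancement ratio for one compound."""

    compound_id: str
    sebm: float
    log_sebm: float
    zone: str | None = None  # "enhancement" | "attenuation" (GSE-based)

    def __post_init__(self) -> None:
        if not (self.sebm > 0):
            raise ValidationError(f"{self.compound_id}: SEBM must be > 0, got {self.sebm}")


def compute_sebm(obs: float, pred_absolv: float, compound_id: str = "") -> SebmRecord:
    """SEBM ratio from observed and ABSOLV-calculated log S0."""
    if not (math.isfinite(obs) and math.isfinite(pred_absolv)):
        raise ValidationError("obs and pred_absolv must be finite")
    log_sebm = obs - pred_absolv
    return SebmRecord(compound_id=compound_id, sebm=10.0 ** log_sebm, log_sebm=log_sebm)


def format_sebm(sebm: float) -> int:
    """Integer table rendering: round half away from zero; < 1 prints as 1."""
    if sebm < 1.0:
        return 1
    return int(math.floor(sebm + 0.5))


def gse_zone(obs: float, pred_gse: float) -> str:
    """'enhancement' iff obs > GSE prediction; ties count as attenuation."""
    if not (math.isfinite(obs) and math.isfinite(pred_gse)):
        raise ValidationError("obs and pred_gse must be finite")
    if obs == pred_gse:
        logger.info("observed equals GSE prediction (%.3f); tie labelled attenuation", obs)
        return "attenuation"
    return "enhancement" if obs > pred_gse else "attenuation"


def sebm_nrot_trend(
    records: Sequence[CompoundRecord],
    obs: np.ndarray,
    absolv_pred: np.ndarray,
) -> tuple[pd.DataFrame, NrotCorrection, WeightedFit, MetricsReport]:
    """log SEBM as a function of nROT: scatter table plus OLS trend line.

    The fit is the same unweighted OLS as the rotatable-bond residual
    correction (log SEBM = obs - ABSOLV is exactly that residual); the
    returned table is plot-ready (nrot, log_sebm, fitted).
    """
    corr, fit, metrics = fit_nrot_correction(records, obs, absolv_pred)
    rows = [
        {
            "id": r.id,
            "nrot": r.nrot,
            "log_sebm": float(o - p),
            "fitted": corr.intercept + corr.slope * r.nrot if r.nrot is not None else np.nan,
        }
        for r, o, p in zip(records, np.asarray(obs, float), np.asarray(absolv_pred, float))
        if r.nrot is not None
    ]
    return pd.DataFrame(rows), corr, fit, metrics
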