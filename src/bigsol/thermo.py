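"""Temperature normalization of solubility and enthalpy-of-solution prediction.

Solubility measurements reported at a temperature other than 25 deg C are
brought to the reference temperature with the van't Hoff relation

    log S0(T_ref) = log S0(T) - (dH_sol / (2.303 R)) (1/T_ref - 1/T)

where dH_sol is the enthalpy of solution.  The ln-10 factor is carried as
2.303 (the printed-arithmetic convention of the source equations, not ln 10
to machine precision; the difference is < 0.001 log for every fixture case).
A compound with positive (endothermic) dH_sol becomes less soluble on
cooling — the naproxen worked example (+29 kJ/mol, 37 -> 25 deg C) drops by
0.2 log.  Most big molecules have negative dH_sol: their solubility falls as
temperature rises, the signature of 'molecular chameleon' conformational
behaviour.

dH_sol itself can be estimated from the Abraham descriptors, with indicator
variables for ionization class (base, neutral, ampholyte; acids are the
all-zero reference class).  High B and large V push dH_sol exothermic.  The
packaged coefficient preset is synthetic: it is a least-squares fit to the
31 enthalpy values of the big-molecule fixture (filename and name carry the
'synthetic' label), not the published prediction equation; supply transcribed
coefficients for production use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import AbrahamDescriptors
from .errors import ConfigurationError, ValidationError

GAS_CONSTANT_R = 8.314  # J/(mol K)
LN10 = 2.303  # printed-arithmetic convention


def normalize_temperature(
    log_s0_at_t: float,
    dh_sol: float,
    t_meas: float,
    t_ref: float = 298.15,
) -> float:
    """Shift log S0 measured at ``t_meas`` (K) to ``t_ref`` (K).

    ``dh_sol`` is the enthalpy of solution in kJ/mol (converted to J/mol
    internally).  The round trip t_meas -> t_ref -> t_meas is exact.
    """
    if t_meas <= 0 or t_ref <= 0:
        raise ValidationError(f"temperatures must be > 0 K, got {t_meas}, {t_ref}")
    if not np.isfinite(dh_sol):
        raise ValidationError(f"dh_sol must be finite, got {dh_sol}")
    slope = dh_sol * 1000.0 / (LN10 * GAS_CONSTANT_R)
    return float(log_s0_at_t - slope * (1.0 / t_ref - 1.0 / t_meas))


@dataclass(frozen=True)
class IonizationIndicators:
    """Indicator variables for the enthalpy model; acid is all-zero."""

    I_B: int = 0
    I_N: int = 0
    I_Z: int = 0

    def __post_init__(self) -> None:
        vals = (self.I_B, self.I_N, self.I_Z)
        if any(v not in (0, 1) for v in vals) or sum(vals) > 1:
            raise ValidationError(f"at most one indicator may be 1, got {vals}")

    @classmethod
    def from_class(cls, ionization: str) -> "IonizationIndicators":
        mapping = {
            "acid": cls(),
            "base": cls(I_B=1),
            "neutral": cls(I_N=1),
            "ampholyte": cls(I_Z=1),
        }
        try:
            return mapping[ionization]
        except KeyError:
            raise ValidationError(f"unknown ionization class {ionization!r}") from None


@dataclass(frozen=True)
class DhSolCoefficients:
    """Linear coefficients for predicting dH_sol (kJ/mol) from descriptors.

    Indicator coefficients default to 0, which reduces the model to the
    descriptor-only variant used when the ionization class is unknown.
    """

    c0: float
    c_A: float
    c_B: float
    c_S: float
    c_E: float
    c_V: float
    c_IB: float = 0.0
    c_IN: float = 0.0
    c_IZ: float = 0.0


DH_SOL_BIG31_SYNTHETIC = DhSolCoefficients(
    c0=34.8229, c_A=-4.4185, c_B=-8.976, c_S=7.9538, c_E=8.6635,
    c_V=-11.5235, c_IB=-0.8703, c_IN=-1.8146, c_IZ=1.5832,
)
"""Synthetic preset: least-squares fit of the big-molecule fixture's
dH_sol column on (1, A, B, S_pi, E, V, I_B, I_N, I_Z); RMSE ~2.3 kJ/mol on
those 31 compounds.  A stand-in for the published prediction equation, which
must be transcribed by the user for production work."""

PRESETS = {"dh-sol-big31-synthetic": DH_SOL_BIG31_SYNTHETIC}


def predict_dh_sol(
    desc: AbrahamDescriptors,
    indicators: IonizationIndicators | None = None,
    coeffs: DhSolCoefficients | None = None,
) -> float:
    """Predict the enthalpy of solution (kJ/mol) from Abraham descriptors.

    ``indicators=None`` behaves as the acid (all-zero) reference class.
    Raises :class:`ConfigurationError` when no coefficient preset is given:
    transcribe the published prediction equation (or pass the synthetic
    fixture-derived preset) first.
    """
    if coeffs is None:
        raise ConfigurationError(
            "no dH_sol coefficient preset configured; transcribe the published "
            "prediction-equation coefficients into a DhSolCoefficients, or use "
            "PRESETS['dh-sol-big31-synthetic'] (fixture-derived stand-in)"
        )
    ind = indicators or IonizationIndicators()
    return float(
        coeffs.c0
        + coeffs.c_A * desc.A
        + coeffs.c_B * desc.B
        + coeffs.c_S * desc.S_pi
        + coeffs.c_E * desc.E
        + coeffs.c_V * desc.V
        + coeffs.c_IB * ind.I_B
        + coeffs.c_IN * ind.I_N
        + coeffs.c_IZ * ind.I_Z
    )
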