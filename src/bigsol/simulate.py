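"""Synthetic small- and big-molecule solubility datasets.

The training database behind the small-molecule models is not public.  This
module generates descriptor tables with the statistical structure the
analysis assumes, so every downstream stage (weighted fits, the exponent
scan, the random forest, the rotatable-bond correction) can be exercised and
validated by parameter recovery.

The small set mimics the published marginals of the training data: mean
clogP 1.89, mean MW 280 Da, mean log S0 near -3.12, heteroscedastic
measurement SDs.  The big set (MW >= 800 Da) mimics the 31-compound
reference set: mean MW ~1034 Da, mean clogP ~3.17, rotatable-bond counts
spanning 3-53, and the shallow-lipophilicity generating law
log S0 = -1.77 - 0.01 (mp - 25) - 0.4 clogP.  Abraham descriptors are drawn
with a shared latent size factor so that bigger molecules carry more H-bond
acceptor strength, reproducing the small/big NHA separation.

One named random stream is used per draw category (mw, mp, clogP,
descriptors, counts, noise, SDs), so adding a field never perturbs earlier
draws and a fixed seed yields byte-identical tables.

No attempt is made to mimic real chemical structures; these are descriptor
tables only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .absolv import ABSOLV_2020, AbsolvCoefficients
from .datasets import AbrahamDescriptors, CompoundRecord, SolubilityEntry
from .errors import ConfigurationError
from .gse import GSE_BIG_2020, GSE_CLASSIC

_STREAMS = {"mw": 0, "mp": 1, "clogp": 2, "descriptors": 3, "counts": 4, "noise": 5, "sds": 6}

#: Default marginal targets.  Small-set mp is centred so that the GSE
#: generating law with the clogP marginal lands near the -3.12 mean log S0
#: of the training data.
SMALL_MARGINALS = {
    "mw": (280.0, 80.0, 120.0, 799.0),     # mean, sd, low, high
    "mp": (198.0, 55.0, 40.0, 350.0),
    "clogp": (1.89, 1.8),
    "A": (0.6, 0.35), "B": (1.2, 0.5), "S_pi": (1.5, 0.6),
    "E": (1.3, 0.6), "V": (1.9, 0.6),
    "nrot": (0, 12),
}
BIG_MARGINALS = {
    "mw": (1034.0, 250.0, 800.0, 2000.0),
    "mp": (185.0, 50.0, 40.0, 350.0),
    "clogp": (3.17, 3.0),
    "A": (2.1, 1.2), "B": (5.9, 2.2), "S_pi": (6.9, 3.0),
    "E": (5.1, 2.0), "V": (7.6, 2.0),
    "nrot": (3, 53),
}

_N_PARAMS = {"gse": 3, "absolv": 7, "absolv_bz": 8}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic generator.

    ``model`` names the generating law ('gse' | 'absolv' | 'absolv_bz');
    ``true_coefficients`` overrides its coefficient vector (defaults:
    the classic GSE for small sets, the big-molecule GSE refit for big sets,
    and the packaged ABSOLV preset for descriptor-based laws).
    ``noise_sd`` is the Gaussian noise on log S0; each entry is also assigned
    a simulated measurement SD drawn uniformly from ``sd_range``.
    """

    n_compounds: int
    seed: int = 0
    model: str = "gse"
    true_coefficients: Sequence[float] | None = None
    noise_sd: float = 0.5
    sd_range: tuple[float, float] = (0.05, 0.7)
    z_true: float | None = None
    c_bz_true: float = 1.0
    marginals: dict | None = None

    def __post_init__(self) -> None:
        if self.model not in _N_PARAMS:
            raise ConfigurationError(f"unknown generating model {self.model!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.sd_range[0] > self.sd_range[1]:
            raise ConfigurationError(f"sd_range low > high: {self.sd_range}")
        if self.model == "absolv_bz" and self.z_true is not None and self.z_true <= 0:
            raise ConfigurationError(f"z_true must be > 0, got {self.z_true}")
        if self.n_compounds < _N_PARAMS[self.model] + 2:
            raise ConfigurationError(
                f"n_compounds = {self.n_compounds} under-determines the "
                f"{_N_PARAMS[self.model]}-parameter {self.model!r} model"
            )


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


def _trunc_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_descriptors(config, marg, mw, mw_mean, mw_sd):
    """Abraham descriptors with a shared latent size factor from MW."""
    rng = _rng(config, "descriptors")
    n = len(mw)
    latent = (mw - mw_mean) / mw_sd
    out = {}
    for name in ("A", "B", "S_pi", "E", "V"):
        mean, sd = marg[name]
        # half the descriptor variance rides on molecular size
        vals = mean + sd * (0.7 * latent + 0.7 * rng.standard_normal(n))
        floor = 0.05 if name in ("B", "V") else 0.0
        out[name] = np.maximum(vals, floor)
    return out


def _generate(config: GeneratorConfig, marg: dict, big: bool, id_prefix: str):
    mw_mean, mw_sd, mw_lo, mw_hi = marg["mw"]
    n = config.n_compounds
    mw = _trunc_normal(_rng(config, "mw"), mw_mean, mw_sd, mw_lo, mw_hi, n)
    mp = _trunc_normal(_rng(config, "mp"), *marg["mp"], n)
    clogp = marg["clogp"][0] + marg["clogp"][1] * _rng(config, "clogp").standard_normal(n)
    desc = _draw_descriptors(config, marg, mw, mw_mean, mw_sd)

    crng = _rng(config, "counts")
    nrot = crng.integers(marg["nrot"][0], marg["nrot"][1] + 1, size=n)
    nha = np.maximum(crng.poisson(15 if big else 4, size=n), 0)
    nhd = np.maximum(crng.poisson(8 if big else 2, size=n), 0)

    if config.model == "gse":
        coeffs = config.true_coefficients
        if coeffs is None:
            preset = GSE_BIG_2020 if big else GSE_CLASSIC
            coeffs = (preset.intercept, preset.mp_coef, preset.logp_coef)
        signal = coeffs[0] + coeffs[1] * (mp - 25.0) + coeffs[2] * clogp
    else:
        c = (np.asarray(config.true_coefficients, dtype=float)
             if config.true_coefficients is not None else ABSOLV_2020.as_array())
        signal = (c[0] + c[1] * desc["A"] + c[2] * desc["B"] + c[3] * desc["S_pi"]
                  + c[4] * desc["E"] + c[5] * desc["V"] + c[6] * desc["A"] * desc["B"])
        if config.model == "absolv_bz":
            if config.z_true is None:
                raise ConfigurationError("absolv_bz generation requires z_true")
            c_bz = c[7] if len(c) > 7 else config.c_bz_true
            signal = signal + c_bz * desc["B"] ** config.z_true

    # Heteroscedastic noise: each entry's declared measurement SD describes
    # its actual noise up to a common scale, with the average noise level
    # equal to noise_sd.  Declared SDs are then correct weights for any
    # downstream inverse-variance fit.
    sds = _rng(config, "sds").uniform(config.sd_range[0], config.sd_range[1], size=n)
    sd_bar = 0.5 * (config.sd_range[0] + config.sd_range[1])
    noise_scale = config.noise_sd * sds / sd_bar
    log_s0 = signal + noise_scale * _rng(config, "noise").standard_normal(n)

    pairs = []
    for i in range(n):
        rec = CompoundRecord(
            id=f"{id_prefix}-{i:05d}",
            name=f"{id_prefix}-{i:05d}",
            mw=float(mw[i]), mp=float(mp[i]), clogp=float(clogp[i]),
            nha=int(nha[i]), nhd=int(nhd[i]), nrot=int(nrot[i]),
            abraham=AbrahamDescriptors(
                A=float(desc["A"][i]), B=float(desc["B"][i]), S_pi=float(desc["S_pi"][i]),
                E=float(desc["E"][i]), V=float(desc["V"][i]),
            ),
        )
        ent = SolubilityEntry(
            compound_id=rec.id, log_s0=float(log_s0[i]), sd=float(sds[i]),
            source="synthetic",
        )
        pairs.append((rec, ent))
    return pairs


def generate_small_set(config: GeneratorConfig) -> list[tuple[CompoundRecord, SolubilityEntry]]:
    """Synthetic small molecules (MW < 800 Da) under the configured law."""
    marg = {**SMALL_MARGINALS, **(config.marginals or {})}
    return _generate(config, marg, big=False, id_prefix="syn-small")


def generate_big_set(config: GeneratorConfig) -> list[tuple[CompoundRecord, SolubilityEntry]]:
    """Synthetic big molecules (MW >= 800 Da); default law is the
    shallow-slope big-molecule GSE refit."""
    marg = {**BIG_MARGINALS, **(config.marginals or {})}
    return _generate(config, marg, big=True, id_prefix="syn-big")


def generate_bz_set(config: GeneratorConfig) -> list[tuple[CompoundRecord, SolubilityEntry]]:
    """Small-molecule set whose generating law adds the nonlinear basicity
    term c_Bz * B**z_true; used to validate exponent-scan recovery.

    The basicity marginal is widened relative to the plain small set so the
    draw spans the small-to-big B range over which the nonlinear term is
    identifiable.
    """
    if config.z_true is None:
        raise ConfigurationError("generate_bz_set requires z_true")
    cfg = config if config.model == "absolv_bz" else GeneratorConfig(
        **{**config.__dict__, "model": "absolv_bz"}
    )
    marg = {**SMALL_MARGINALS, "B": (3.0, 2.0), **(config.marginals or {})}
    return _generate(cfg, marg, big=False, id_prefix="syn-bz")
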