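"""Study orchestration: load or simulate -> predict -> SEBM -> report.

``run_study`` regenerates the big-molecule analysis end to end for a
compound table (by default the packaged 31-compound fixture): per-compound
GSE and ABSOLV predictions from the named presets, the SEBM ratio and GSE
zoning, the rotatable-bond residual correction, and a metric report for each
prediction column.  Everything is written to the output directory as CSV /
JSON, along with a manifest (package version, seeds, presets, input) that is
sufficient to replay the run; outputs carry no timestamps, so identical
configurations reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .absolv import PRESETS as ABSOLV_PRESETS
from .absolv import apply_nrot_correction, fit_nrot_correction, predict_absolv
from .datasets import load_big31, load_compound_table, pairs_to_frame
from .errors import ConfigurationError
from .forest import ForestModel, build_descriptor_table, predict_rfr
from .gse import PRESETS as GSE_PRESETS
from .gse import predict_gse
from .regression import evaluate
from .sebm import compute_sebm, format_sebm, gse_zone

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one study run."""

    input_csv: str | None = None        # None -> packaged big-molecule fixture
    models: tuple[str, ...] = ("gse", "absolv")
    gse_preset: str = "gse-classic"
    absolv_preset: str = "absolv-2020"
    rfr_model: ForestModel | None = None
    nrot_correct: bool = True
    threshold: float = 0.5
    seed: int = 0
    outdir: str = "bigsol-run"
    default_sd: float | None = 0.5


def run_study(config: PipelineConfig) -> Path:
    """Execute the pipeline; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_csv is None:
        pairs = load_big31(default_sd=config.default_sd)
        input_name = "packaged:big31"
    else:
        pairs = load_compound_table(config.input_csv, default_sd=config.default_sd)
        input_name = str(config.input_csv)
    records = [r for r, _ in pairs]
    obs = np.array([e.log_s0 for _, e in pairs])
    logger.info("loaded %d compounds from %s", len(records), input_name)

    table = pd.DataFrame({"id": [r.id for r in records], "obs": obs})
    metrics: dict[str, dict] = {}

    if "gse" in config.models:
        if config.gse_preset not in GSE_PRESETS:
            raise ConfigurationError(f"unknown GSE preset {config.gse_preset!r}")
        coeffs = GSE_PRESETS[config.gse_preset]
        table["gse"] = [predict_gse(r.mp, r.clogp, coeffs) for r in records]
        table["gse_zone"] = [gse_zone(o, p) for o, p in zip(obs, table["gse"])]
        metrics["gse"] = evaluate(obs, table["gse"].to_numpy(),
                                  threshold=config.threshold, n_params=2).to_dict()

    if "absolv" in config.models:
        if config.absolv_preset not in ABSOLV_PRESETS:
            raise ConfigurationError(f"unknown ABSOLV preset {config.absolv_preset!r}")
        coeffs = ABSOLV_PRESETS[config.absolv_preset]
        table["absolv"] = [predict_absolv(r.abraham, coeffs) for r in records]
        metrics["absolv"] = evaluate(obs, table["absolv"].to_numpy(),
                                     threshold=config.threshold, n_params=6).to_dict()
        sebm_records = [compute_sebm(o, p, r.id)
                        for r, o, p in zip(records, obs, table["absolv"])]
        table["log_sebm"] = [s.log_sebm for s in sebm_records]
        table["sebm"] = [format_sebm(s.sebm) for s in sebm_records]
        if config.nrot_correct:
            corr, _, corr_metrics = fit_nrot_correction(records, obs, table["absolv"].to_numpy())
            table["absolv_nrot"] = apply_nrot_correction(corr, records, table["absolv"].to_numpy())
            metrics["nrot_line"] = {**corr_metrics.to_dict(),
                                    "intercept": round(corr.intercept, 3),
                                    "slope": round(corr.slope, 3)}
            metrics["absolv_nrot"] = evaluate(obs, table["absolv_nrot"].to_numpy(),
                                              threshold=config.threshold, n_params=6).to_dict()

    if config.rfr_model is not None:
        feats = build_descriptor_table(records)
        table["rfr"] = predict_rfr(config.rfr_model, feats)
        metrics["rfr"] = evaluate(obs, table["rfr"].to_numpy(),
                                  threshold=config.threshold).to_dict()

    table.to_csv(outdir / "predictions.csv", index=False)
    pairs_to_frame(pairs).to_csv(outdir / "compounds.csv", index=False)
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    manifest = {
        "package": "bigsol",
        "version": __version__,
        "input": input_name,
        "n_compounds": len(records),
        "config": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config) if f.name != "rfr_model"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run written to %s", outdir)
    return outdir
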