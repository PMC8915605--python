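"""Data model and I/O for intrinsic-solubility compound tables.

The package works on tabular records of drug-like compounds: identity,
physicochemical descriptors (melting point, clogP, molecular weight, H-bond
counts, rotatable bonds), Abraham solvation descriptors, and measured
intrinsic aqueous solubility log S0 (log molar) with an estimated measurement
SD.  Compounds are partitioned into 'big' (MW >= 800 Da, the beyond-Rule-of-5
set) and 'small' molecules.

Two reference tables are packaged as fixtures:

* ``big31_properties.csv`` — the 31 big molecules with all descriptors and
  per-compound averaged log S0 values;
* ``big31_reference_predictions.csv`` — observed log S0 next to the GSE,
  ABSOLV and random-forest predictions and the SEBM enhancement ratio for
  the same 31 compounds.

The ionization column of the property fixture is a package annotation
assigned from the standard acid-base behaviour of each drug (the two
iodinated contrast-agent diacids are acids; macrolide/ketolide antibiotics
are bases; polyenes, glycopeptides, rifamycins and most peptides are
ampholytes; the remainder neutral).  It feeds only the indicator variables
of the enthalpy-of-solution model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

BIG_MW_THRESHOLD = 800.0
"""Molecular-weight demarcation (Da) between 'small' and 'big' molecules."""

IONIZATION_CLASSES = ("acid", "base", "neutral", "ampholyte")

#: Canonical CSV column names.  ``load_compound_table`` accepts a mapping from
#: these canonical names to whatever the file actually calls them.
REQUIRED_COLUMNS = ("id", "log_s0", "mp", "clogp", "mw")
OPTIONAL_COLUMNS = (
    "name", "sd", "n_sources", "dh_sol", "nha", "nhd", "nrot",
    "A", "B", "S_pi", "E", "V", "ionization", "temperature", "source",
    "smiles",
)


@dataclass(frozen=True)
class AbrahamDescriptors:
    """Abraham solvation descriptors of a solute.

    A: total H-bond acidity; B: total H-bond basicity; S_pi:
    dipolarity/polarizability; E: excess molar refraction in
    (cm^3/mol)/10; V: McGowan characteristic volume in (cm^3/mol)/100.
    The A*B product and the nonlinear B**z term are derived on demand.
    """

    A: float
    B: float
    S_pi: float
    E: float
    V: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValidationError(f"Abraham A and B must be >= 0, got A={self.A}, B={self.B}")
        if self.V <= 0:
            raise ValidationError(f"McGowan volume V must be > 0, got V={self.V}")

    @property
    def AB(self) -> float:
        """Acid-base cross term A*B."""
        return self.A * self.B

    def B_pow(self, z: float) -> float:
        """Nonlinear basicity term B**z; defined as 0 for B = 0 (any z > 0)."""
        if z <= 0:
            raise ValidationError(f"exponent z must be > 0, got {z}")
        if self.B == 0.0:
            return 0.0
        return self.B ** z


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's identity, descriptors and ionization class."""

    id: str
    name: str = ""
    mw: float = float("nan")
    mp: float | None = None
    clogp: float | None = None
    nha: int | None = None
    nhd: int | None = None
    nrot: int | None = None
    ionization: str = "neutral"
    abraham: AbrahamDescriptors | None = None
    dh_sol: float | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not (self.mw > 0):
            raise ValidationError(f"{self.id}: molecular weight must be > 0, got {self.mw}")
        for fname in ("nha", "nhd", "nrot"):
            v = getattr(self, fname)
            if v is not None and (v < 0 or int(v) != v):
                raise ValidationError(f"{self.id}: {fname} must be a non-negative integer, got {v}")
        if self.ionization not in IONIZATION_CLASSES:
            raise ValidationError(
                f"{self.id}: ionization must be one of {IONIZATION_CLASSES}, got {self.ionization!r}"
            )

    @property
    def size_class(self) -> str:
        """'big' iff MW >= 800 Da, else 'small'."""
        return "big" if self.mw >= BIG_MW_THRESHOLD else "small"


@dataclass(frozen=True)
class SolubilityEntry:
    """One measured intrinsic solubility value (log10 molar)."""

    compound_id: str
    log_s0: float
    sd: float | None = None
    temperature: float = 298.15
    source: str = ""
    n_sources: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_s0):
            raise ValidationError(f"{self.compound_id}: log_s0 must be finite, got {self.log_s0}")
        if self.sd is not None and self.sd < 0:
            raise ValidationError(f"{self.compound_id}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ReferencePredictionRow:
    """One row of the packaged reference prediction table."""

    compound_id: str
    obs: float
    gse: float
    absolv: float
    rfr: float
    sebm: float

    def __post_init__(self) -> None:
        if not (self.sebm > 0):
            raise ValidationError(f"{self.compound_id}: SEBM ratio must be > 0, got {self.sebm}")


# ---------------------------------------------------------------------------
# Loading and writing compound tables
# ---------------------------------------------------------------------------

def _to_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"row {row}, column {column!r}: cannot parse {value!r} as a number") from exc


def _to_int(value, row: int, column: str) -> int | None:
    v = _to_float(value, row, column)
    return None if v is None else int(v)


def load_compound_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    *,
    default_sd: float | None = None,
) -> list[tuple[CompoundRecord, SolubilityEntry]]:
    """Load a compound CSV into validated (record, entry) pairs.

    Parameters
    ----------
    path : file path of a UTF-8, comma-separated table with a header row.
    schema : optional mapping {canonical name: column name in file}; columns
        not mentioned are matched by canonical name. Column order is
        irrelevant.
    default_sd : SD assigned to entries lacking one (log units); ``None``
        leaves the SD missing (downstream weighting applies its own floor).

    Rows violating a domain invariant are rejected; each rejection is logged
    with the row index and reason, and valid rows are still returned.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    schema = schema or {}
    colmap = {canon: schema.get(canon, canon) for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    missing = [colmap[c] for c in REQUIRED_COLUMNS if colmap[c] not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    def get(row, canon):
        col = colmap[canon]
        return row.get(col) if col in frame.columns else None

    pairs: list[tuple[CompoundRecord, SolubilityEntry]] = []
    for i, row in frame.iterrows():
        try:
            abraham = None
            desc = {d: _to_float(get(row, d), i, colmap[d]) for d in ("A", "B", "S_pi", "E", "V")}
            if all(v is not None for v in desc.values()):
                abraham = AbrahamDescriptors(**desc)
            ionization = get(row, "ionization")
            record = CompoundRecord(
                id=str(get(row, "id")),
                name=str(get(row, "name") or ""),
                mw=_to_float(get(row, "mw"), i, colmap["mw"]),
                mp=_to_float(get(row, "mp"), i, colmap["mp"]),
                clogp=_to_float(get(row, "clogp"), i, colmap["clogp"]),
                nha=_to_int(get(row, "nha"), i, colmap["nha"]),
                nhd=_to_int(get(row, "nhd"), i, colmap["nhd"]),
                nrot=_to_int(get(row, "nrot"), i, colmap["nrot"]),
                ionization=str(ionization) if isinstance(ionization, str) and ionization else "neutral",
                abraham=abraham,
                dh_sol=_to_float(get(row, "dh_sol"), i, colmap["dh_sol"]),
                smiles=(str(get(row, "smiles")) if isinstance(get(row, "smiles"), str) else None),
            )
            sd = _to_float(get(row, "sd"), i, colmap["sd"])
            if sd is None:
                sd = default_sd
            temp = _to_float(get(row, "temperature"), i, colmap["temperature"])
            source = get(row, "source")
            entry = SolubilityEntry(
                compound_id=record.id,
                log_s0=_to_float(get(row, "log_s0"), i, colmap["log_s0"]),
                sd=sd,
                temperature=temp if temp is not None else 298.15,
                source=str(source) if isinstance(source, str) else "",
                n_sources=_to_int(get(row, "n_sources"), i, colmap["n_sources"]),
            )
        except ParseError:
            raise
        except (ValidationError, TypeError) as exc:
            logger.warning("row %d rejected: %s", i, exc)
            continue
        pairs.append((record, entry))
    return pairs


def write_compound_table(pairs: Sequence[tuple[CompoundRecord, SolubilityEntry]], path: str | Path) -> None:
    """Write (record, entry) pairs to the canonical CSV schema."""
    rows = []
    for rec, ent in pairs:
        row = {
            "id": rec.id, "name": rec.name, "log_s0": ent.log_s0, "sd": ent.sd,
            "n_sources": ent.n_sources, "mw": rec.mw, "mp": rec.mp, "clogp": rec.clogp,
            "dh_sol": rec.dh_sol, "nha": rec.nha, "nhd": rec.nhd, "nrot": rec.nrot,
            "ionization": rec.ionization, "temperature": ent.temperature,
            "source": ent.source, "smiles": rec.smiles,
        }
        if rec.abraham is not None:
            row.update(A=rec.abraham.A, B=rec.abraham.B, S_pi=rec.abraham.S_pi,
                       E=rec.abraham.E, V=rec.abraham.V)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def pairs_to_frame(pairs: Sequence[tuple[CompoundRecord, SolubilityEntry]]) -> pd.DataFrame:
    """Flatten (record, entry) pairs into a DataFrame (one row per compound)."""
    rows = []
    for rec, ent in pairs:
        row = {
            "id": rec.id, "name": rec.name, "mw": rec.mw, "mp": rec.mp,
            "clogp": rec.clogp, "nha": rec.nha, "nhd": rec.nhd, "nrot": rec.nrot,
            "ionization": rec.ionization, "dh_sol": rec.dh_sol,
            "log_s0": ent.log_s0, "sd": ent.sd, "temperature": ent.temperature,
            "size_class": rec.size_class,
        }
        if rec.abraham is not None:
            row.update(A=rec.abraham.A, B=rec.abraham.B, S_pi=rec.abraham.S_pi,
                       E=rec.abraham.E, V=rec.abraham.V, AB=rec.abraham.AB)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Partitioning and summaries
# ---------------------------------------------------------------------------

def big_small_split(
    records: Iterable[CompoundRecord],
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Partition records into (big, small) by MW >= 800 Da, order preserved."""
    big, small = [], []
    for rec in records:
        (big if rec.size_class == "big" else small).append(rec)
    return big, small


def summarize_properties(
    records: Sequence[CompoundRecord],
    entries: Sequence[SolubilityEntry],
    *,
    bins: int = 10,
) -> dict:
    """Per-size-class property summary: means of log S0, clogP, MW and
    NHA/NHD histograms.

    Means are per-compound (each record contributes once, paired with its
    averaged solubility entry).
    """
    if len(records) == 0:
        raise ValidationError("cannot summarize an empty record set")
    if len(records) != len(entries):
        raise ValidationError("records and entries must be parallel sequences")
    frame = pairs_to_frame(list(zip(records, entries)))
    out: dict = {"classes": {}}
    for cls, sub in frame.groupby("size_class"):
        hist = {}
        for col in ("nha", "nhd"):
            vals = sub[col].dropna().to_numpy()
            if len(vals):
                counts, edges = np.histogram(vals, bins=bins)
                hist[col] = {"counts": counts.tolist(), "edges": edges.tolist()}
        out["classes"][cls] = {
            "n": int(len(sub)),
            "mean_log_s0": float(sub["log_s0"].mean()),
            "mean_clogp": float(sub["clogp"].mean()),
            "mean_mw": float(sub["mw"].mean()),
            "histograms": hist,
        }
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(fname: str):
    return resources.files("bigsol.fixtures").joinpath(fname)


def load_big31(default_sd: float | None = None) -> list[tuple[CompoundRecord, SolubilityEntry]]:
    """The packaged 31-compound big-molecule property table."""
    with resources.as_file(_fixture_path("big31_properties.csv")) as p:
        return load_compound_table(p, default_sd=default_sd)


def load_big31_reference() -> list[ReferencePredictionRow]:
    """The packaged reference predictions (observed, GSE, ABSOLV, RFR, SEBM)."""
    with resources.as_file(_fixture_path("big31_reference_predictions.csv")) as p:
        frame = pd.read_csv(p, dtype={"id": str})
    return [
        ReferencePredictionRow(
            compound_id=row["id"], obs=row["obs"], gse=row["gse"],
            absolv=row["absolv"], rfr=row["rfr"], sebm=float(row["sebm"]),
        )
        for _, row in frame.iterrows()
    ]


def load_big31_reference_frame() -> pd.DataFrame:
    """Reference prediction table as a DataFrame indexed like the property fixture."""
    with resources.as_file(_fixture_path("big31_reference_predictions.csv")) as p:
        return pd.read_csv(p, dtype={"id": str})
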