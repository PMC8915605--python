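"""Random-forest regression of log S0 on a combined descriptor table.

The feature table combines the melting point and the five Abraham
descriptors with an optional block of 2D structural descriptors — either
computed with RDKit from SMILES when structures are available, or supplied
as a precomputed CSV.  Columns that are zero for every compound are dropped
before fitting.

The forest uses the classic defaults (500 trees, a third of the features
tried per split, unlimited depth), which are near-optimal for solubility
QSPR without tuning.  A seeded random 70/30 compound split provides the
train / internal-validation pair of metric reports; feature importances
(mean decrease in impurity, normalized to sum 1) are reported in descending
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .datasets import CompoundRecord
from .errors import ValidationError
from .regression import MetricsReport, evaluate

logger = logging.getLogger(__name__)

MIN_ROWS = 50

_CORE_FEATURES = ("mp", "A", "B", "S_pi", "E", "V")


def _rdkit_descriptors(smiles: Sequence[str | None]) -> pd.DataFrame | None:
    """2D descriptor block from RDKit, or None when unavailable/absent."""
    if not any(smiles):
        return None
    try:
        from rdkit import Chem
        from rdkit.Chem import Descriptors
    except ImportError:
        logger.warning("RDKit not importable; structural descriptors skipped")
        return None
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            rows.append({})
            continue
        rows.append(Descriptors.CalcMolDescriptors(mol))
    return pd.DataFrame(rows)


def build_descriptor_table(
    records: Sequence[CompoundRecord],
    extra_descriptors: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the aligned feature matrix for forest training.

    Core features are mp and the five Abraham descriptors.  ``extra_descriptors``
    (indexed like ``records``, one row per compound) contributes the 2D
    structural block; when absent and records carry SMILES, RDKit computes
    it; otherwise the reduced core set is used with a warning.  All-zero
    columns are dropped and logged; a feature-name collision raises.
    """
    core = pd.DataFrame({
        "mp": [r.mp for r in records],
        "A": [r.abraham.A if r.abraham else np.nan for r in records],
        "B": [r.abraham.B if r.abraham else np.nan for r in records],
        "S_pi": [r.abraham.S_pi if r.abraham else np.nan for r in records],
        "E": [r.abraham.E if r.abraham else np.nan for r in records],
        "V": [r.abraham.V if r.abraham else np.nan for r in records],
    }, index=[r.id for r in records])
    if core.isna().any().any():
        raise ValidationError("all records need mp and Abraham descriptors")

    block = extra_descriptors
    if block is None:
        block = _rdkit_descriptors([r.smiles for r in records])
    if block is None:
        logger.warning("no structural descriptors available; using the reduced "
                       "feature set (mp + 5 Abraham descriptors)")
        table = core
    else:
        block = block.reset_index(drop=True)
        block.index = core.index
        collisions = set(core.columns) & set(block.columns)
        if collisions:
            raise ValidationError(f"feature-name collision(s): {sorted(collisions)}")
        table = pd.concat([core, block], axis=1)

    numeric = table.select_dtypes(include=[np.number]).fillna(0.0)
    all_zero = [c for c in numeric.columns if (numeric[c] == 0).all()]
    if all_zero:
        logger.info("dropping %d all-zero descriptor column(s): %s", len(all_zero), all_zero)
        numeric = numeric.drop(columns=all_zero)
    return numeric


@dataclass
class ForestModel:
    """A fitted random forest plus its feature manifest and importances."""

    estimator: RandomForestRegressor
    feature_names: list[str]
    n_trees: int
    seed: int
    importance: pd.Series  # normalized, sorted descending


def train_rfr(
    table: pd.DataFrame,
    targets: np.ndarray,
    *,
    test_size: float = 0.3,
    seed: int = 0,
    n_trees: int = 500,
    max_features: float = 1 / 3,
) -> tuple[ForestModel, MetricsReport, MetricsReport]:
    """Fit a random forest on a seeded random 70/30 compound split.

    Returns the model and (train, validation) metric reports.
    """
    if len(table) < MIN_ROWS:
        raise ValidationError(f"need >= {MIN_ROWS} rows to train, got {len(table)}")
    y = np.asarray(targets, dtype=float)
    if len(y) != len(table):
        raise ValidationError("targets must align with the descriptor table")
    X_tr, X_va, y_tr, y_va = train_test_split(table, y, test_size=test_size, random_state=seed)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features, random_state=seed, n_jobs=1,
    )
    forest.fit(X_tr.to_numpy(), y_tr)
    imp = pd.Series(forest.feature_importances_, index=table.columns)
    imp = (imp / imp.sum()).sort_values(ascending=False)
    model = ForestModel(
        estimator=forest, feature_names=list(table.columns),
        n_trees=n_trees, seed=seed, importance=imp,
    )
    train_metrics = evaluate(y_tr, forest.predict(X_tr.to_numpy()))
    valid_metrics = evaluate(y_va, forest.predict(X_va.to_numpy()))
    return model, train_metrics, valid_metrics


def predict_rfr(model: ForestModel, table: pd.DataFrame) -> np.ndarray:
    """Ensemble-mean predictions; the table must cover the model's features."""
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValidationError(f"missing feature(s): {missing}")
    return model.estimator.predict(table[model.feature_names].to_numpy())
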