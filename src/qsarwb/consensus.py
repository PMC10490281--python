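"""Intelligent consensus prediction: combining several models' predictions.

Four strategies over a compounds × models prediction matrix:

* ``CM0`` — arithmetic mean over all models;
* ``CM1`` — mean over *qualified* models;
* ``CM2`` — weighted mean over qualified models (weights ∝ 1 / LOO MAE);
* ``CM3`` — per-compound pick of the locally best qualified model, judged
  by its mean absolute leave-one-out residual over the query's k nearest
  training neighbours.

A model qualifies when its training-set leave-one-out MAE is within a
configurable factor (default 1.5×) of the best model's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import DescriptorTable
from .exceptions import ConfigError, DomainError
from .models import MLRModel
from .validation import _loo_predictions

__all__ = ["ConsensusSet", "combine", "intelligent_consensus", "STRATEGIES"]

STRATEGIES = ("CM0", "CM1", "CM2", "CM3")


@dataclass
class ConsensusSet:
    """Per-model predictions plus qualification flags and consensus outputs."""

    predictions: pd.DataFrame            # compounds × models
    qualified: dict[str, bool]
    weights: dict[str, float]            # normalized over qualified models
    loo_mae: dict[str, float]
    consensus: dict[str, pd.Series] = field(default_factory=dict)  # per strategy
    cm3_picks: pd.Series | None = None


def combine(
    predictions: pd.DataFrame,
    strategy: str,
    qualified: dict[str, bool] | None = None,
    weights: dict[str, float] | None = None,
    picks: pd.Series | None = None,
) -> pd.Series:
    """Combine a compounds × models prediction matrix under one strategy.

    Low-level entry point: qualification flags, weights and per-compound
    picks are supplied by the caller (see :func:`intelligent_consensus` for
    the full pipeline). Falls back to CM0 with a warning when no model
    qualifies.
    """
    if strategy not in STRATEGIES:
        raise ConfigError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if predictions.shape[1] < 2:
        raise DomainError("consensus needs at least 2 models")
    if strategy == "CM0":
        return predictions.mean(axis=1)
    qualified = qualified or {}
    q_models = [m for m in predictions.columns if qualified.get(m, False)]
    if not q_models:
        warnings.warn("no model qualifies; falling back to CM0")
        return predictions.mean(axis=1)
    if strategy == "CM1":
        return predictions[q_models].mean(axis=1)
    if strategy == "CM2":
        if not weights:
            raise ConfigError("CM2 requires weights")
        w = np.array([weights[m] for m in q_models], dtype=float)
        w = w / w.sum()
        return pd.Series(predictions[q_models].to_numpy() @ w, index=predictions.index)
    # CM3
    if picks is None:
        raise ConfigError("CM3 requires per-compound picks")
    out = pd.Series(index=predictions.index, dtype=float)
    for cid in predictions.index:
        out[cid] = predictions.loc[cid, picks[cid]]
    return out


def _model_matrix(models: dict[str, MLRModel], table: DescriptorTable) -> pd.DataFrame:
    return pd.DataFrame(
        {name: m.predict(table.X) for name, m in models.items()},
        index=table.X.index,
    )


def intelligent_consensus(
    models: dict[str, MLRModel],
    train: DescriptorTable,
    test: DescriptorTable,
    strategies=STRATEGIES,
    qualification_factor: float = 1.5,
    k_neighbors: int = 5,
) -> ConsensusSet:
    """Full consensus pipeline over fitted MLR models.

    Computes per-model training LOO residuals, qualification flags
    (LOO MAE ≤ ``qualification_factor`` × best), CM2 weights ∝ 1/LOO-MAE,
    and CM3 per-compound picks by the smallest mean |LOO residual| over the
    ``k_neighbors`` nearest training compounds (Euclidean distance on the
    standardized union of the models' descriptors).
    """
    if len(models) < 2:
        raise DomainError("consensus needs at least 2 models")
    names = list(models)
    loo_resid: dict[str, np.ndarray] = {}
    loo_mae: dict[str, float] = {}
    y = train.activity.to_numpy()
    for name in names:
        cols = models[name].descriptor_names
        loo_pred = _loo_predictions(train.X[cols].to_numpy(), y)
        loo_resid[name] = y - loo_pred
        loo_mae[name] = float(np.mean(np.abs(loo_resid[name])))
    best = min(loo_mae.values())
    qualified = {m: loo_mae[m] <= qualification_factor * best for m in names}
    q_models = [m for m in names if qualified[m]]
    raw_w = {m: 1.0 / loo_mae[m] for m in q_models}
    total = sum(raw_w.values())
    weights = {m: raw_w[m] / total for m in q_models}

    predictions = _model_matrix(models, test)

    # CM3 neighbourhoods on the standardized shared descriptor space
    shared = sorted({c for m in models.values() for c in m.descriptor_names})
    Xtr = train.X[shared].to_numpy()
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Ztr = (Xtr - mu) / sd
    Zte = (test.X[shared].to_numpy() - mu) / sd
    k = min(k_neighbors, len(train.X))
    picks = {}
    pick_pool = q_models if q_models else names
    for row, cid in zip(Zte, test.X.index):
        d = np.linalg.norm(Ztr - row, axis=1)
        nn = np.argsort(d, kind="stable")[:k]
        local = {m: float(np.mean(np.abs(loo_resid[m][nn]))) for m in pick_pool}
        picks[cid] = min(sorted(local), key=lambda m: local[m])
    picks = pd.Series(picks)

    out = ConsensusSet(
        predictions=predictions,
        qualified=qualified,
        weights=weights,
        loo_mae=loo_mae,
        cm3_picks=picks,
    )
    for strat in strategies:
        out.consensus[strat] = combine(
            predictions, strat, qualified=qualified, weights=weights, picks=picks
        )
    return out
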