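"""Minimal horizontal federated-learning simulator.

Emulates the canonical hub topology — each institution trains a local
logistic-regression update on its own records and a central model store
aggregates the coefficients (FedAvg) — together with a centralized
baseline trained on the pooled data with the identical optimizer.

The local optimizer is deliberately plain full-batch gradient descent
on the mean logistic loss (mini-batch available via config): with one
local epoch and record-count aggregation weights, one FedAvg round is
algebraically identical to one centralized full-batch step on the
pooled data, which pins the simulator to its baseline exactly rather
than approximately. Features are standardized with pooled statistics
before training so coefficient magnitudes are comparable across
features.

All randomness (splitting, mini-batch shuffling) flows from the config
seed; a run result is a pure function of (data, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .data_model import (
    InstitutionDataset,
    PartitionManifest,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FLConfig:
    """Hyperparameters of one federated (or centralized) training run."""

    n_rounds: int = 50
    local_epochs: int = 1
    learning_rate: float = 0.5
    batch_size: int | Literal["full"] = "full"
    seed: int = 0
    aggregation_weights: Literal["by_record_count", "uniform"] = "by_record_count"

    def __post_init__(self):
        if self.n_rounds < 1 or self.local_epochs < 1:
            raise ValidationError("n_rounds and local_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.batch_size != "full" and self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1 or 'full'")

    def to_dict(self) -> dict:
        return {
            "n_rounds": self.n_rounds,
            "local_epochs": self.local_epochs,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "aggregation_weights": self.aggregation_weights,
        }


@dataclass(frozen=True)
class FLRunResult:
    """Trained global model plus per-round training history."""

    coefficients: np.ndarray
    intercept: float
    round_history: list[dict[str, float]]
    pooled_loss_history: list[float]
    heldout_accuracy: float | None
    config: FLConfig
    feature_means: np.ndarray
    feature_stds: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class predictions on raw (unstandardized) feature rows."""
        Z = (np.asarray(X, float) - self.feature_means) / self.feature_stds
        return (Z @ self.coefficients + self.intercept > 0).astype(int)

    def accuracy(self, dataset: InstitutionDataset) -> float:
        if dataset.labels is None:
            raise ValidationError("dataset must carry labels")
        pred = self.predict(dataset.numeric_matrix())
        return float(np.mean(pred == np.asarray(dataset.labels, int)))


def split_dataset(
    data: InstitutionDataset,
    sizes: Sequence[int],
    seed: int,
    institution_ids: Sequence[str] | None = None,
) -> tuple[list[InstitutionDataset], PartitionManifest]:
    """Randomly partition one dataset into disjoint institutions.

    The partition is exhaustive (every record assigned exactly once) and
    a pure function of the seed.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 0 for s in sizes):
        raise ValidationError("sizes must be non-negative")
    if sum(sizes) != data.n_records:
        raise ValidationError(
            f"sizes sum to {sum(sizes)} but dataset has {data.n_records} records"
        )
    if institution_ids is None:
        institution_ids = [f"institution{i + 1}" for i in range(len(sizes))]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_records)
    ids_all = data.effective_record_ids()
    parts: list[InstitutionDataset] = []
    start = 0
    for iid, size in zip(institution_ids, sizes):
        idx = np.sort(perm[start : start + size])
        start += size
        parts.append(
            InstitutionDataset(
                institution_id=iid,
                values=data.values[idx],
                missing=data.missing[idx],
                schema=data.schema,
                labels=None if data.labels is None else data.labels[idx],
                record_ids=[ids_all[i] for i in idx],
            )
        )
    manifest = PartitionManifest.from_datasets(parts, seed=seed)
    return parts, manifest


# ---------------------------------------------------------------------------
# Logistic-regression training loop
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_loss(X, y, w, b) -> float:
    z = X @ w + b
    # log(1 + exp(-z*s)) with s = ±1, stable form
    s = 2.0 * y - 1.0
    m = -z * s
    return float(np.mean(np.logaddexp(0.0, m)))


def _design(dataset: InstitutionDataset):
    X = dataset.numeric_matrix()
    if np.isnan(X).any():
        raise ValidationError(
            "training requires fully observed numeric features "
            f"({dataset.institution_id!r} has missing or unparseable cells)"
        )
    if dataset.labels is None:
        raise ValidationError(f"{dataset.institution_id!r} has no labels")
    return X, np.asarray(dataset.labels, dtype=float)


def _local_update(X, y, w, b, config: FLConfig, rng: np.random.Generator):
    """local_epochs of (mini-)batch gradient descent from (w, b)."""
    n = len(y)
    for _ in range(config.local_epochs):
        if config.batch_size == "full" or config.batch_size >= n:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            bs = int(config.batch_size)
            batches = [order[i : i + bs] for i in range(0, n, bs)]
        for idx in batches:
            Xb, yb = X[idx], y[idx]
            resid = _sigmoid(Xb @ w + b) - yb
            w = w - config.learning_rate * (Xb.T @ resid) / len(idx)
            b = b - config.learning_rate * float(resid.mean())
    return w, b


def fedavg_train(
    partitions: Sequence[InstitutionDataset],
    config: FLConfig,
    heldout: InstitutionDataset | None = None,
) -> FLRunResult:
    """FedAvg over logistic regression across institutional partitions.

    Per round every non-empty institution takes ``local_epochs``
    gradient steps from the current global coefficients on its own
    standardized records; the global model becomes the aggregation-
    weighted average of the local coefficients. ``round_history[r]``
    maps institution id to its local training loss after its update.
    """
    active = [p for p in partitions if p.n_records > 0]
    for p in partitions:
        if p.n_records == 0:
            logger.warning(
                "institution %r is empty and excluded from training",
                p.institution_id,
            )
    if not active:
        raise ValidationError("need at least one non-empty partition")

    data = [_design(p) for p in active]
    X_all = np.vstack([X for X, _ in data])
    y_all = np.concatenate([y for _, y in data])
    if len(np.unique(y_all)) < 2:
        raise ValidationError("pooled training data has a single class")
    mu = X_all.mean(axis=0)
    sd = X_all.std(axis=0)
    sd[sd == 0] = 1.0
    data = [((X - mu) / sd, y) for X, y in data]
    Z_all = (X_all - mu) / sd

    n_i = np.array([len(y) for _, y in data], dtype=float)
    if config.aggregation_weights == "by_record_count":
        agg = n_i / n_i.sum()
    else:
        agg = np.full(len(data), 1.0 / len(data))

    p_feat = Z_all.shape[1]
    w = np.zeros(p_feat)
    b = 0.0
    round_history: list[dict[str, float]] = []
    pooled_loss: list[float] = []
    rngs = [
        np.random.default_rng([config.seed, k]) for k in range(len(active))
    ]
    for _ in range(config.n_rounds):
        local_ws, local_bs, losses = [], [], {}
        for k, ((Xk, yk), part) in enumerate(zip(data, active)):
            wk, bk = _local_update(Xk, yk, w, b, config, rngs[k])
            local_ws.append(wk)
            local_bs.append(bk)
            losses[part.institution_id] = _log_loss(Xk, yk, wk, bk)
        w = np.sum([a * wk for a, wk in zip(agg, local_ws)], axis=0)
        b = float(np.sum([a * bk for a, bk in zip(agg, local_bs)]))
        round_history.append(losses)
        pooled_loss.append(_log_loss(Z_all, y_all, w, b))

    result = FLRunResult(
        coefficients=w,
        intercept=b,
        round_history=round_history,
        pooled_loss_history=pooled_loss,
        heldout_accuracy=None,
        config=config,
        feature_means=mu,
        feature_stds=sd,
    )
    if heldout is not None:
        result = replace(result, heldout_accuracy=result.accuracy(heldout))
    return result


def centralized_train(
    data: InstitutionDataset,
    config: FLConfig,
    heldout: InstitutionDataset | None = None,
) -> FLRunResult:
    """Centralized baseline: identical optimizer, one institution."""
    if data.n_records < 1:
        raise ValidationError("need at least one record")
    if data.labels is None or len(np.unique(np.asarray(data.labels))) < 2:
        raise ValidationError("centralized training needs both classes")
    return fedavg_train([data], config, heldout=heldout)
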