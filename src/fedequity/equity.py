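"""Contribution shares, the composite report, and the Gini summary.

Two normalized-share equations underpin contribution equity in a
federated collaboration of n institutions:

* model contribution of institution i:  M_i / sum_j M_j, where
  M_i in [0, 1] is the institution's model-development contribution
  level (in the worked two-institution example this is the per-
  institution Dice similarity, normalized);
* data contribution of institution i:  D_i / N, where D_i is the
  institution's record count and N the collaboration's total.

The composite report blends the five agreed components — completeness,
heterogeneity, quantity, conformance, provenance — by configurable
non-negative weights into one normalized share vector, and summarises
share inequality with the discrete Gini coefficient

    G = sum_i sum_j |x_i - x_j| / (2 n^2 mu).

Heterogeneity can enter either as similarity (an institution close to
the pool scores high) or as dissimilarity (diverse data is rewarded, 1
minus similarity); both modes are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ValidationError
from .quality import QualityScores

COMPONENTS = ("completeness", "heterogeneity", "quantity", "conformance", "provenance")

DEFAULT_WEIGHTS = {c: 1.0 for c in COMPONENTS}


class UndefinedShareError(ValueError):
    """Shares are undefined when the normalizing total is zero."""


def model_contribution_shares(levels: Sequence[float]) -> list[float]:
    """Normalize model-contribution levels M_i to shares M_i / ΣM_j."""
    lv = np.asarray(list(levels), dtype=float)
    if lv.size == 0:
        raise ValidationError("need at least one contribution level")
    if np.any(lv < 0):
        raise ValidationError("contribution levels must be >= 0")
    total = lv.sum()
    if total <= 0:
        raise UndefinedShareError("all contribution levels are zero")
    return [float(x) for x in lv / total]


def data_contribution_share(records_i: int, total_records: int) -> float:
    """Record-count share D_i / N of one institution."""
    if total_records <= 0:
        raise UndefinedShareError("total record count N must be positive")
    if not 0 <= records_i <= total_records:
        raise ValidationError("records_i must satisfy 0 <= D_i <= N")
    return records_i / total_records


def gini_coefficient(shares: Sequence[float]) -> float:
    """Discrete Gini inequality index of a non-negative share vector.

    Mean-absolute-difference form, no small-sample correction:
    0 for perfectly equal shares, approaching (n-1)/n < 1 when one
    institution holds everything. Invariant to uniform scaling.
    """
    x = np.asarray(list(shares), dtype=float)
    if x.size == 0:
        raise ValidationError("need at least one share")
    if np.any(x < 0):
        raise ValidationError("shares must be non-negative")
    mu = x.mean()
    if mu <= 0:
        raise UndefinedShareError("all shares are zero")
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * x.size**2 * mu))


def lorenz_curve(shares: Sequence[float]) -> pd.DataFrame:
    """Cumulative population vs cumulative share table for Lorenz plots."""
    x = np.sort(np.asarray(list(shares), dtype=float))
    if x.sum() <= 0:
        raise UndefinedShareError("all shares are zero")
    cum = np.concatenate([[0.0], np.cumsum(x) / x.sum()])
    pop = np.arange(x.size + 1) / x.size
    return pd.DataFrame({"cumulative_population": pop, "cumulative_share": cum})


@dataclass(frozen=True)
class ContributionInputs:
    """Validated inputs to the composite contribution report.

    ``model_levels`` are the M_i in [0, 1]; ``record_counts`` the D_i
    with N their sum; ``heterogeneity`` the per-institution Dice
    similarity in [0, 1]; ``weights`` non-negative component weights
    over exactly the five agreed components (uniform by default — the
    collaboration contract is expected to fix them).
    """

    institution_ids: tuple[str, ...]
    model_levels: Mapping[str, float]
    record_counts: Mapping[str, int]
    quality: Mapping[str, QualityScores]
    heterogeneity: Mapping[str, float]
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self):
        ids = tuple(self.institution_ids)
        object.__setattr__(self, "institution_ids", ids)
        if not ids:
            raise ValidationError("need at least one institution")
        for m in (self.model_levels, self.record_counts, self.quality, self.heterogeneity):
            if set(m) != set(ids):
                raise ValidationError("per-institution maps must cover all institutions")
        for iid in ids:
            if not 0.0 <= self.model_levels[iid] <= 1.0:
                raise ValidationError(f"model level for {iid!r} must be in [0,1]")
            if not 0.0 <= self.heterogeneity[iid] <= 1.0:
                raise ValidationError(f"heterogeneity for {iid!r} must be in [0,1]")
            if self.record_counts[iid] < 0:
                raise ValidationError("record counts must be >= 0")
        if set(self.weights) != set(COMPONENTS):
            raise ValidationError(
                f"weights must cover exactly the components {COMPONENTS}"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be non-negative")
        if sum(self.weights.values()) <= 0:
            raise ValidationError("weights must sum to a positive value")

    @property
    def total_records(self) -> int:
        return sum(self.record_counts.values())


@dataclass(frozen=True)
class ContributionReport:
    """Per-institution shares, component scores, and inequality summary."""

    institution_ids: tuple[str, ...]
    model_shares: dict[str, float]
    data_shares: dict[str, float]
    component_scores: dict[str, dict[str, float]]
    composite_shares: dict[str, float]
    gini: float
    mode: str

    def __post_init__(self):
        object.__setattr__(self, "institution_ids", tuple(self.institution_ids))
        for name in ("model_shares", "data_shares", "composite_shares"):
            vec = getattr(self, name)
            if vec and abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1")

    def to_dict(self) -> dict:
        return {
            "institution_ids": list(self.institution_ids),
            "model_shares": dict(self.model_shares),
            "data_shares": dict(self.data_shares),
            "component_scores": {k: dict(v) for k, v in self.component_scores.items()},
            "composite_shares": dict(self.composite_shares),
            "gini": self.gini,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ContributionReport":
        return cls(
            institution_ids=tuple(d["institution_ids"]),
            model_shares=dict(d["model_shares"]),
            data_shares=dict(d["data_shares"]),
            component_scores={k: dict(v) for k, v in d["component_scores"].items()},
            composite_shares=dict(d["composite_shares"]),
            gini=d["gini"],
            mode=d["mode"],
        )


def composite_report(
    inputs: ContributionInputs,
    mode: Literal["similarity", "dissimilarity"] = "similarity",
) -> ContributionReport:
    """Blend the five components into normalized composite shares.

    Per institution the raw score is the weighted mean of completeness,
    the heterogeneity term (similarity s_i, or 1 - s_i in dissimilarity
    mode), the quantity share D_i/N, the mean of the three conformance
    sub-scores, and provenance; raw scores are then normalized to sum
    to 1 exactly as model levels are.
    """
    if mode not in ("similarity", "dissimilarity"):
        raise ValidationError(f"unknown mode {mode!r}")
    ids = inputs.institution_ids
    n_total = inputs.total_records
    w = inputs.weights
    w_sum = sum(w.values())

    component_scores: dict[str, dict[str, float]] = {}
    raw = []
    for iid in ids:
        q = inputs.quality[iid]
        s = inputs.heterogeneity[iid]
        het = s if mode == "similarity" else 1.0 - s
        comp = {
            "completeness": q.completeness,
            "heterogeneity": het,
            "quantity": data_contribution_share(q.quantity, n_total)
            if n_total > 0
            else 0.0,
            "conformance": q.conformance.mean,
            "provenance": q.provenance,
            "similarity": s,
        }
        component_scores[iid] = comp
        raw.append(sum(w[c] * comp[c] for c in COMPONENTS) / w_sum)

    composite = model_contribution_shares(raw)
    model = model_contribution_shares([inputs.model_levels[i] for i in ids])
    data = [
        data_contribution_share(inputs.record_counts[i], n_total) for i in ids
    ]

    return ContributionReport(
        institution_ids=ids,
        model_shares=dict(zip(ids, model)),
        data_shares=dict(zip(ids, data)),
        component_scores=component_scores,
        composite_shares=dict(zip(ids, composite)),
        gini=gini_coefficient(composite),
        mode=mode,
    )
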