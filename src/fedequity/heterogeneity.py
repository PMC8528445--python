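"""Inter-institutional similarity via the Sørensen–Dice coefficient.

Each institution's tabular data is reduced to a multiset ("bag") of
tokens: for a continuous feature, the token is ``(feature, bin index)``
with bins fit by pooled quantiles; for a categorical feature it is
``(feature, category)``. Two bags A and B are compared with the multiset
Dice coefficient

    D(A, B) = 2 * sum_t min(A_t, B_t) / (|A| + |B|)

which is 1 for identical bags and 0 for disjoint token support, and —
unlike the plain set form — respects differing record counts. A low
similarity against the pooled collaboration data marks an institution as
contributing heterogeneous (diverse) records.

Shannon entropy (in bits) is provided as the complementary
information-content profile of a value distribution.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import InstitutionDataset, Schema, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 10


class UndefinedSimilarityError(ValueError):
    """Dice similarity is undefined when both bags are empty."""


class UndefinedEntropyError(ValueError):
    """Entropy is undefined for an empty count distribution."""


class DegenerateFeatureError(ValueError):
    """Raised when a feature has no non-missing pooled values to bin."""


@dataclass(frozen=True)
class TokenBag:
    """Multiset of (feature, bin-or-category) tokens for one dataset."""

    counts: Mapping[tuple, int]

    def __post_init__(self):
        object.__setattr__(
            self, "counts", {t: int(c) for t, c in self.counts.items() if c}
        )
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("token counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "TokenBag") -> "TokenBag":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return TokenBag(merged)


@dataclass(frozen=True)
class BinningSpec:
    """Per-feature quantile cut points fitted on pooled data.

    ``edges[name]`` holds the interior cut points (strictly increasing,
    at most ``n_bins - 1`` of them; fewer when pooled quantiles
    coincide, down to zero for a constant feature, which then maps every
    value to the single bin 0). A value v lands in bin
    ``searchsorted(edges, v, side='right')`` — half-open intervals with
    values beyond the fitted range clamped to the boundary bins.
    """

    n_bins: int
    edges: Mapping[str, tuple[float, ...]]

    def __post_init__(self):
        for name, e in self.edges.items():
            arr = np.asarray(e, dtype=float)
            if arr.size and not np.all(np.diff(arr) > 0):
                raise ValidationError(
                    f"bin edges for {name!r} must be strictly increasing"
                )

    def bin_index(self, feature: str, value: float) -> int:
        return int(
            np.searchsorted(np.asarray(self.edges[feature]), value, side="right")
        )

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "edges": {k: list(v) for k, v in self.edges.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BinningSpec":
        return cls(
            n_bins=int(d["n_bins"]),
            edges={k: tuple(v) for k, v in d["edges"].items()},
        )


def fit_binning(
    datasets: Sequence[InstitutionDataset], n_bins: int = DEFAULT_N_BINS
) -> BinningSpec:
    """Fit per-feature quantile bin edges on the pooled (union) data.

    Continuous and binary features get interior edges at the pooled
    ``k/n_bins`` quantiles (duplicates dropped); categorical features
    need no binning and get no entry.
    """
    if not datasets:
        raise ValidationError("need at least one dataset to fit binning")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    schema = datasets[0].schema
    mats = [d.numeric_matrix() for d in datasets]
    pooled = np.vstack(mats) if mats else np.empty((0, schema.n_features))
    edges: dict[str, tuple[float, ...]] = {}
    for j, spec in enumerate(schema.features):
        if spec.dtype == "categorical":
            continue
        col = pooled[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            raise DegenerateFeatureError(
                f"feature {spec.name!r} has no non-missing pooled values"
            )
        qs = np.quantile(col, np.arange(1, n_bins) / n_bins)
        uniq = np.unique(qs)
        # a constant feature collapses to zero interior edges: one bin
        uniq = uniq[(uniq > col.min()) | (uniq < col.max())]
        edges[spec.name] = tuple(float(x) for x in uniq)
    return BinningSpec(n_bins=n_bins, edges=edges)


def tokenize(dataset: InstitutionDataset, binning: BinningSpec) -> TokenBag:
    """Reduce a dataset to its (feature, bin/category) multiset.

    Missing cells contribute no token; the bag total is therefore the
    dataset's non-missing cell count. Numeric values outside the fitted
    edges clamp to the boundary bins (logged, not an error).
    """
    counts: Counter = Counter()
    mat = dataset.numeric_matrix()
    n_clamped = 0
    for j, spec in enumerate(dataset.schema.features):
        if spec.dtype == "categorical":
            for i in range(dataset.n_records):
                if not dataset.missing[i, j]:
                    counts[(spec.name, str(dataset.values[i, j]))] += 1
            continue
        e = np.asarray(binning.edges.get(spec.name, ()), dtype=float)
        col = mat[:, j]
        ok = ~np.isnan(col)
        if e.size:
            n_clamped += int(np.sum(ok & ((col < e[0]) | (col >= e[-1]))))
        bins = np.searchsorted(e, col[ok], side="right")
        for b, c in zip(*np.unique(bins, return_counts=True)):
            counts[(spec.name, int(b))] += int(c)
    if n_clamped:
        logger.debug(
            "%s: %d values fell in the boundary bins of the fitted edges",
            dataset.institution_id,
            n_clamped,
        )
    return TokenBag(counts)


def dice_coefficient(a: TokenBag, b: TokenBag) -> float:
    """Multiset Sørensen–Dice similarity, 2·Σ min / (|A|+|B|), in [0, 1]."""
    ta, tb = a.total, b.total
    if ta + tb == 0:
        raise UndefinedSimilarityError("both token bags are empty")
    overlap = sum(min(c, b.counts.get(t, 0)) for t, c in a.counts.items())
    return 2.0 * overlap / (ta + tb)


def institution_similarity_scores(
    datasets: Sequence[InstitutionDataset],
    reference: Literal["pooled", "leave_one_out"] = "pooled",
    n_bins: int = DEFAULT_N_BINS,
    binning: BinningSpec | None = None,
) -> dict[str, float]:
    """Per-institution Dice similarity against a reference bag.

    ``pooled`` compares each institution to the union of all
    institutions (itself included); ``leave_one_out`` compares it to the
    union of the others. One score per institution either way.
    """
    if len(datasets) < 2:
        raise ValidationError("need at least two institutions")
    if binning is None:
        binning = fit_binning(datasets, n_bins=n_bins)
    bags = {d.institution_id: tokenize(d, binning) for d in datasets}
    for iid, bag in bags.items():
        if bag.total == 0:
            raise UndefinedSimilarityError(
                f"institution {iid!r} has an empty token bag"
            )
    pooled_bag = TokenBag(Counter())
    for bag in bags.values():
        pooled_bag = pooled_bag + bag
    scores = {}
    for iid, bag in bags.items():
        if reference == "pooled":
            ref = pooled_bag
        elif reference == "leave_one_out":
            rest = Counter(pooled_bag.counts)
            rest.subtract(bag.counts)
            ref = TokenBag(rest)
        else:
            raise ValidationError(f"unknown reference mode {reference!r}")
        scores[iid] = dice_coefficient(bag, ref)
    return scores


def shannon_entropy(counts: Mapping | Sequence[float]) -> float:
    """Shannon entropy of a count distribution, in bits.

    Accepts a mapping value -> count or a bare sequence of counts.
    Bounded by ``log2(k)`` for k distinct values, attained iff uniform.
    """
    if isinstance(counts, Mapping):
        vals = np.asarray(list(counts.values()), dtype=float)
    else:
        vals = np.asarray(list(counts), dtype=float)
    if vals.size == 0 or vals.sum() <= 0:
        raise UndefinedEntropyError("entropy of an empty distribution")
    if np.any(vals < 0):
        raise ValidationError("counts must be non-negative")
    return float(stats.entropy(vals, base=2))
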