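"""Data-quality components of contribution: completeness, conformance,
provenance.

Together with heterogeneity (Dice similarity) and quantity (record
count), these are the five agreed components on which contribution
shares are computed. All scores are fractions in [0, 1] and monotone in
the obvious direction: adding a missing cell never raises completeness,
satisfying one more checklist item never lowers provenance.

Conformance is split in three, each checked against the bound schema:

* value conformance — fraction of non-missing cells inside the schema's
  allowed ranges;
* relational conformance — 1 minus the duplicate record-identity
  fraction;
* computational conformance — fraction of non-missing cells parseable
  as their declared dtype.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .data_model import InstitutionDataset, Schema, ValidationError

logger = logging.getLogger(__name__)


class UndefinedScoreError(ValueError):
    """Raised for scores that are undefined on empty input."""


@dataclass(frozen=True)
class ConformanceScores:
    value: float
    relational: float
    computational: float

    def __post_init__(self):
        for name in ("value", "relational", "computational"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} conformance must be in [0,1]")

    @property
    def mean(self) -> float:
        return (self.value + self.relational + self.computational) / 3.0


@dataclass(frozen=True)
class QualityScores:
    """Per-institution component scores feeding the equity report."""

    completeness: float
    quantity: int
    conformance: ConformanceScores
    provenance: float

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ValidationError("completeness must be in [0,1]")
        if not 0.0 <= self.provenance <= 1.0:
            raise ValidationError("provenance must be in [0,1]")
        if self.quantity < 0:
            raise ValidationError("quantity must be >= 0")

    def to_dict(self) -> dict:
        return {
            "completeness": self.completeness,
            "quantity": self.quantity,
            "conformance": {
                "value": self.conformance.value,
                "relational": self.conformance.relational,
                "computational": self.conformance.computational,
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QualityScores":
        return cls(
            completeness=d["completeness"],
            quantity=d["quantity"],
            conformance=ConformanceScores(**d["conformance"]),
            provenance=d["provenance"],
        )


@dataclass(frozen=True)
class ProvenanceChecklist:
    """Declarative lineage documentation: item name -> satisfied?

    Typical items: source documented, capture date present,
    transformation log present, consent/IRB reference present, data
    steward identified.
    """

    items: Mapping[str, bool]

    def __post_init__(self):
        if not self.items:
            raise ValidationError("checklist needs at least one item")
        object.__setattr__(
            self, "items", {str(k): bool(v) for k, v in self.items.items()}
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ProvenanceChecklist":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls(items=data)


def completeness_score(dataset: InstitutionDataset) -> float:
    """1 minus the fraction of missing cells."""
    if dataset.n_records == 0:
        raise UndefinedScoreError("completeness undefined for zero records")
    return 1.0 - float(dataset.missing.mean())


def conformance_scores(
    dataset: InstitutionDataset, schema: Schema | None = None
) -> ConformanceScores:
    """Value / relational / computational conformance of a dataset.

    If no feature declares an allowed range, value conformance is
    reported as 1.0 with a logged warning (nothing to check).
    """
    schema = schema or dataset.schema
    mat = dataset.numeric_matrix()

    # value conformance: non-missing cells of range-constrained features
    checked = 0
    in_range = 0
    any_range = False
    for j, spec in enumerate(schema.features):
        if spec.allowed_range is None:
            continue
        any_range = True
        for i in range(dataset.n_records):
            if dataset.missing[i, j]:
                continue
            checked += 1
            if spec.dtype == "categorical":
                if str(dataset.values[i, j]) in spec.allowed_range:
                    in_range += 1
            else:
                lo, hi = spec.allowed_range
                v = mat[i, j]
                if not np.isnan(v) and lo <= v <= hi:
                    in_range += 1
    if not any_range:
        logger.warning(
            "schema declares no allowed ranges; value conformance is vacuous"
        )
        value = 1.0
    else:
        value = in_range / checked if checked else 1.0

    # relational conformance: duplicate record identities
    ids = dataset.effective_record_ids()
    if ids:
        relational = len(set(ids)) / len(ids)
    else:
        relational = 1.0

    # computational conformance: dtype-parseability of non-missing cells
    total = 0
    parseable = 0
    for j, spec in enumerate(schema.features):
        for i in range(dataset.n_records):
            if dataset.missing[i, j]:
                continue
            total += 1
            v = dataset.values[i, j]
            if spec.dtype == "categorical":
                parseable += 1
            elif spec.dtype == "binary":
                try:
                    parseable += float(v) in (0.0, 1.0)
                except (TypeError, ValueError):
                    pass
            else:
                try:
                    float(v)
                    parseable += 1
                except (TypeError, ValueError):
                    pass
    computational = parseable / total if total else 1.0

    return ConformanceScores(
        value=value, relational=relational, computational=computational
    )


def provenance_score(checklist: ProvenanceChecklist) -> float:
    """Fraction of satisfied lineage-documentation items."""
    items = list(checklist.items.values())
    return sum(items) / len(items)


def score_dataset(
    dataset: InstitutionDataset,
    checklist: ProvenanceChecklist | None = None,
) -> QualityScores:
    """Bundle all non-heterogeneity components for one institution.

    With no checklist, provenance defaults to 0 (nothing documented).
    """
    prov = provenance_score(checklist) if checklist is not None else 0.0
    return QualityScores(
        completeness=completeness_score(dataset),
        quantity=dataset.n_records,
        conformance=conformance_scores(dataset),
        provenance=prov,
    )
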