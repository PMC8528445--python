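"""Schema binding, institutional dataset containers, and file I/O.

A horizontal federated-learning collaboration consists of several
institutions that each hold tabular records over a shared feature space.
This module provides the in-memory containers for one institution's data
(:class:`InstitutionDataset`), the agreed feature contract
(:class:`Schema`), and the bookkeeping for how a pooled dataset was
partitioned (:class:`PartitionManifest`), together with CSV/JSON/YAML
readers and writers.

CSV conventions: RFC 4180, comma separated, UTF-8, header row required.
Empty fields and the tokens ``NA`` / ``NaN`` (case-insensitive) are
treated as missing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING_TOKENS = frozenset({"", "na", "nan"})

FEATURE_DTYPES = ("continuous", "categorical", "binary")


class SchemaMismatchError(ValueError):
    """Raised when a file's columns do not match the bound schema."""


class CellParseError(ValueError):
    """Raised when a cell cannot be parsed as its declared dtype.

    Carries ``row`` (0-based data row) and ``column`` (feature name).
    """

    def __init__(self, row: int, column: str, value: str):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"cell at row {row}, column {column!r} is not parseable "
            f"as its declared dtype: {value!r}"
        )


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


def _is_missing_token(raw: str) -> bool:
    return raw.strip().lower() in MISSING_TOKENS


@dataclass(frozen=True)
class FeatureSpec:
    """One feature in the agreed schema.

    ``allowed_range`` is an inclusive ``(min, max)`` pair for continuous
    or binary features, or a set of allowed categories for categorical
    features. ``None`` means unconstrained (value conformance is then
    vacuously satisfied for this feature).
    """

    name: str
    dtype: str = "continuous"
    allowed_range: tuple[float, float] | frozenset[str] | None = None

    def __post_init__(self):
        if self.dtype not in FEATURE_DTYPES:
            raise ValidationError(
                f"feature {self.name!r}: dtype must be one of {FEATURE_DTYPES}"
            )
        rng = self.allowed_range
        if rng is not None:
            if self.dtype == "categorical":
                object.__setattr__(self, "allowed_range", frozenset(map(str, rng)))
            else:
                lo, hi = float(rng[0]), float(rng[1])
                if lo > hi:
                    raise ValidationError(
                        f"feature {self.name!r}: allowed_range min > max"
                    )
                object.__setattr__(self, "allowed_range", (lo, hi))


@dataclass(frozen=True)
class Schema:
    """Ordered feature contract shared by every institution.

    This is the reference standard that conformance scoring checks
    contributed data against: declared dtypes (computational
    conformance), allowed ranges (value conformance), and the identity
    column (relational conformance).
    """

    features: tuple[FeatureSpec, ...]
    label_column: str | None = None
    id_column: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValidationError("feature names must be unique")
        if not names:
            raise ValidationError("schema must declare at least one feature")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_dict(self) -> dict:
        feats = []
        for f in self.features:
            rng = f.allowed_range
            if isinstance(rng, frozenset):
                rng = sorted(rng)
            elif rng is not None:
                rng = list(rng)
            feats.append({"name": f.name, "dtype": f.dtype, "allowed_range": rng})
        return {
            "features": feats,
            "label_column": self.label_column,
            "id_column": self.id_column,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Schema":
        feats = tuple(
            FeatureSpec(
                name=f["name"],
                dtype=f.get("dtype", "continuous"),
                allowed_range=(
                    tuple(f["allowed_range"])
                    if f.get("allowed_range") is not None
                    and f.get("dtype", "continuous") != "categorical"
                    else (
                        frozenset(f["allowed_range"])
                        if f.get("allowed_range") is not None
                        else None
                    )
                ),
            )
            for f in d["features"]
        )
        return cls(
            features=feats,
            label_column=d.get("label_column"),
            id_column=d.get("id_column"),
        )

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "Schema":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class InstitutionDataset:
    """One institution's records bound to the shared schema.

    ``values`` is an object matrix of raw cell values (floats for parsed
    numeric cells, strings otherwise, ``None`` where missing) and
    ``missing`` the boolean mask of the same shape. Raw strings are kept
    so that conformance scoring can measure parseability instead of
    assuming it.
    """

    institution_id: str
    values: np.ndarray
    missing: np.ndarray
    schema: Schema
    labels: np.ndarray | None = None
    record_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=object)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != self.missing.shape:
            raise ValidationError("missing mask shape must match values shape")
        if self.values.shape[1] != self.schema.n_features:
            raise ValidationError(
                f"dataset has {self.values.shape[1]} columns but schema "
                f"declares {self.schema.n_features} features"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_records:
                raise ValidationError("labels length must equal n_records")
        if self.record_ids is not None:
            self.record_ids = [str(r) for r in self.record_ids]
            if len(self.record_ids) != self.n_records:
                raise ValidationError("record_ids length must equal n_records")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def effective_record_ids(self) -> list[str]:
        """Record identities: explicit IDs, else (institution_id, row)."""
        if self.record_ids is not None:
            return list(self.record_ids)
        return [f"{self.institution_id}:{i}" for i in range(self.n_records)]

    def numeric_matrix(self) -> np.ndarray:
        """Float view of the records; missing or unparseable cells are NaN."""
        out = np.full(self.values.shape, np.nan)
        for j in range(self.n_features):
            for i in range(self.n_records):
                if self.missing[i, j]:
                    continue
                v = self.values[i, j]
                try:
                    out[i, j] = float(v)
                except (TypeError, ValueError):
                    pass
        return out

    def to_frame(self) -> pd.DataFrame:
        """Raw cells as a DataFrame (missing -> NA), for display/export."""
        df = pd.DataFrame(self.values, columns=self.schema.feature_names)
        return df.mask(pd.DataFrame(self.missing, columns=df.columns))


@dataclass(frozen=True)
class PartitionManifest:
    """Accounting of how N pooled records were assigned to institutions."""

    total_records: int
    assignments: dict[str, int]
    seed: int | None = None

    def __post_init__(self):
        if any(c < 0 for c in self.assignments.values()):
            raise ValidationError("assignment counts must be >= 0")
        if sum(self.assignments.values()) != self.total_records:
            raise ValidationError(
                "assignment counts must sum to total_records"
            )

    @classmethod
    def from_datasets(
        cls, datasets: Sequence[InstitutionDataset], seed: int | None = None
    ) -> "PartitionManifest":
        counts = {d.institution_id: d.n_records for d in datasets}
        return cls(total_records=sum(counts.values()), assignments=counts, seed=seed)

    def to_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "assignments": dict(self.assignments),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, spec: FeatureSpec, row: int, strict: bool):
    """Returns (value, missing). Numeric dtypes parse to float."""
    if _is_missing_token(raw):
        return None, True
    if spec.dtype in ("continuous", "binary"):
        try:
            return float(raw), False
        except ValueError:
            if strict:
                raise CellParseError(row, spec.name, raw) from None
            return raw, False
    return raw, False


def read_institution_csv(
    path: str | Path,
    schema: Schema,
    institution_id: str | None = None,
    strict: bool = True,
) -> InstitutionDataset:
    """Read one institution's CSV into a schema-bound dataset.

    The header must contain exactly the schema's feature names (any
    column order), plus the schema's label/ID columns if declared.
    Missing cells (empty, ``NA``, ``NaN``) are masked.  With
    ``strict=True`` an unparseable numeric cell raises
    :class:`CellParseError`; with ``strict=False`` the raw string is
    kept so conformance scoring can count it.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    want = set(schema.feature_names)
    extra_ok = {c for c in (schema.label_column, schema.id_column) if c}
    have = set(df.columns)
    missing_cols = want - have
    extra_cols = have - want - extra_ok
    if missing_cols or extra_cols:
        raise SchemaMismatchError(
            f"CSV columns do not match schema: missing {sorted(missing_cols)}, "
            f"unexpected {sorted(extra_cols)}"
        )
    n = len(df)
    p = schema.n_features
    values = np.empty((n, p), dtype=object)
    mask = np.zeros((n, p), dtype=bool)
    for j, spec in enumerate(schema.features):
        col = df[spec.name].tolist()
        for i, raw in enumerate(col):
            values[i, j], mask[i, j] = _parse_cell(raw, spec, i, strict)

    labels = None
    if schema.label_column and schema.label_column in df.columns:
        labels = np.array(
            [int(float(v)) for v in df[schema.label_column]], dtype=int
        )
    record_ids = None
    if schema.id_column and schema.id_column in df.columns:
        record_ids = df[schema.id_column].tolist()

    return InstitutionDataset(
        institution_id=institution_id or path.stem,
        values=values,
        missing=mask,
        schema=schema,
        labels=labels,
        record_ids=record_ids,
    )


def write_institution_csv(dataset: InstitutionDataset, path: str | Path) -> None:
    """Write a dataset back to CSV (missing cells as empty fields)."""
    cols: dict[str, list] = {}
    if dataset.schema.id_column and dataset.record_ids is not None:
        cols[dataset.schema.id_column] = dataset.record_ids
    for j, spec in enumerate(dataset.schema.features):
        col = []
        for i in range(dataset.n_records):
            if dataset.missing[i, j]:
                col.append("")
            else:
                v = dataset.values[i, j]
                col.append(repr(v) if isinstance(v, float) else str(v))
        cols[spec.name] = col
    if dataset.schema.label_column and dataset.labels is not None:
        cols[dataset.schema.label_column] = [int(v) for v in dataset.labels]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report JSON I/O (the ContributionReport type lives in fedequity.equity;
# serialization is centralised here with the other writers)
# ---------------------------------------------------------------------------


def write_report_json(report, path: str | Path) -> None:
    """Serialize a ContributionReport to JSON, losslessly round-trippable."""
    from .equity import ContributionReport  # local import avoids a cycle

    if not isinstance(report, ContributionReport):
        raise ValidationError("expected a ContributionReport")
    if not report.institution_ids:
        raise ValidationError("report must cover at least one institution")
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def read_report_json(path: str | Path):
    from .equity import ContributionReport

    return ContributionReport.from_dict(json.loads(Path(path).read_text()))
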