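"""Synthetic multi-institution tabular data with controllable pathology.

Generates two-class datasets from a class-conditional Gaussian model:
feature j of a record with label y is drawn N(shift_kj ± effect_j / 2, 1)
for institution k, where ``effect_size`` sets the class-mean separation
in standardized units (so logistic regression is the correctly
specified model and utility / feature-importance tests have known
ground truth) and ``institution_shift`` scales random per-institution
mean offsets, the knob that makes institutions heterogeneous. Missing
cells and out-of-range value violations are injected at stated rates.
Everything is a pure function of the seed.

``wisconsin_like_fixture`` produces the canonical two-class test case:
569 records with 30 continuous features and an imbalanced binary label,
a synthetic stand-in with the same shape and a comparable class split
as the classic breast-cancer diagnostic table (it does not reproduce
that table's values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    FeatureSpec,
    InstitutionDataset,
    Schema,
    ValidationError,
)

ALLOWED_RANGE = (-15.0, 15.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic multi-institution draw."""

    n_institutions: int = 2
    records_per_institution: tuple[int, ...] = (227, 342)
    n_features: int = 30
    class_balance: float = 0.5
    effect_size: float | tuple[float, ...] = 1.0
    institution_shift: float = 0.0
    missing_rate: float = 0.0
    violation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self,
            "records_per_institution",
            tuple(int(r) for r in self.records_per_institution),
        )
        if self.n_institutions < 1 or self.n_features < 1:
            raise ValidationError("counts must be >= 1")
        if len(self.records_per_institution) != self.n_institutions:
            raise ValidationError(
                "records_per_institution must list one count per institution"
            )
        if any(r < 1 for r in self.records_per_institution):
            raise ValidationError("records per institution must be >= 1")
        for name in ("class_balance", "missing_rate", "violation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1]")
        eff = np.atleast_1d(np.asarray(self.effect_size, dtype=float))
        if not np.all(np.isfinite(eff)):
            raise ValidationError("effect sizes must be finite")
        if self.institution_shift < 0:
            raise ValidationError("institution_shift must be >= 0")

    def effect_vector(self) -> np.ndarray:
        eff = np.atleast_1d(np.asarray(self.effect_size, dtype=float))
        if eff.size == 1:
            return np.full(self.n_features, float(eff[0]))
        if eff.size != self.n_features:
            raise ValidationError("per-feature effect sizes must match n_features")
        return eff


def make_schema(n_features: int) -> Schema:
    return Schema(
        features=tuple(
            FeatureSpec(name=f"feature_{j:02d}", dtype="continuous",
                        allowed_range=ALLOWED_RANGE)
            for j in range(n_features)
        ),
        label_column="label",
        id_column="record_id",
    )


def generate_institutions(
    spec: GeneratorSpec,
) -> tuple[list[InstitutionDataset], Schema]:
    """Draw one multi-institution dataset from the generative model."""
    rng = np.random.default_rng(spec.seed)
    schema = make_schema(spec.n_features)
    eff = spec.effect_vector()
    # per-institution mean offsets: scaled standard-normal directions
    shifts = spec.institution_shift * rng.standard_normal(
        (spec.n_institutions, spec.n_features)
    )
    datasets = []
    for k, n_k in enumerate(spec.records_per_institution):
        y = (rng.random(n_k) < spec.class_balance).astype(int)
        means = shifts[k] + (y[:, None] - 0.5) * eff[None, :]
        X = means + rng.standard_normal((n_k, spec.n_features))

        missing = rng.random(X.shape) < spec.missing_rate
        violate = (rng.random(X.shape) < spec.violation_rate) & ~missing
        X = np.where(violate, ALLOWED_RANGE[1] + 10.0 + np.abs(X), X)

        values = np.empty(X.shape, dtype=object)
        for i in range(n_k):
            for j in range(spec.n_features):
                values[i, j] = None if missing[i, j] else float(X[i, j])
        datasets.append(
            InstitutionDataset(
                institution_id=f"institution{k + 1}",
                values=values,
                missing=missing,
                schema=schema,
                labels=y,
                record_ids=[f"institution{k + 1}-{i}" for i in range(n_k)],
            )
        )
    return datasets, schema


def wisconsin_like_fixture(seed: int = 0) -> tuple[InstitutionDataset, Schema]:
    """Synthetic 569-record, 30-feature, two-class diagnostic table.

    Class balance and per-feature effect sizes are fixed so the positive
    class holds roughly 37% of records and a standardized logistic model
    separates the classes well but not perfectly, mirroring the shape
    and difficulty of the classic benchmark without copying its values.
    """
    effects = tuple(np.linspace(1.2, 0.05, 30))
    spec = GeneratorSpec(
        n_institutions=1,
        records_per_institution=(569,),
        n_features=30,
        class_balance=212 / 569,
        effect_size=effects,
        institution_shift=0.0,
        missing_rate=0.0,
        violation_rate=0.0,
        seed=seed,
    )
    datasets, schema = generate_institutions(spec)
    ds = datasets[0]
    ds.institution_id = "pooled"
    ds.record_ids = [f"record-{i}" for i in range(ds.n_records)]
    return ds, schema


def write_institution_dir(
    datasets: Sequence[InstitutionDataset],
    schema: Schema,
    directory: str | Path,
) -> None:
    """Write institution CSVs plus schema.yaml in the CLI's layout."""
    from .data_model import write_institution_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema.to_file(directory / "schema.yaml")
    for ds in datasets:
        write_institution_csv(ds, directory / f"{ds.institution_id}.csv")
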