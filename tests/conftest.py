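import numpy as np
import pytest
from hypothesis import settings

from fedequity import FeatureSpec, InstitutionDataset, Schema

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_dataset(
    institution_id,
    matrix,
    schema=None,
    labels=None,
    record_ids=None,
    missing=None,
):
    """Build an InstitutionDataset from a plain numeric matrix.

    ``None`` entries in the matrix become missing cells.
    """
    matrix = [list(row) for row in matrix]
    n = len(matrix)
    p = len(matrix[0]) if n else 0
    if schema is None:
        schema = Schema(
            features=tuple(
                FeatureSpec(name=f"f{j}", dtype="continuous") for j in range(p)
            ),
            label_column="label" if labels is not None else None,
            id_column="rid" if record_ids is not None else None,
        )
    values = np.empty((n, p), dtype=object)
    mask = np.zeros((n, p), dtype=bool)
    for i in range(n):
        for j in range(p):
            v = matrix[i][j]
            if v is None:
                values[i, j] = None
                mask[i, j] = True
            else:
                values[i, j] = float(v) if not isinstance(v, str) else v
    if missing is not None:
        mask = np.asarray(missing, dtype=bool)
    return InstitutionDataset(
        institution_id=institution_id,
        values=values,
        missing=mask,
        schema=schema,
        labels=labels,
        record_ids=record_ids,
    )


@pytest.fixture
def two_feature_schema():
    return Schema(
        features=(
            FeatureSpec("age", "continuous", (0.0, 120.0)),
            FeatureSpec("stage", "categorical", {"I", "II", "III"}),
        ),
        label_column="outcome",
        id_column="patient_id",
    )
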