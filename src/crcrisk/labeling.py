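"""Boolean labelling of cohort records.

Each value is labelled 1 ("possibly tumor-related") when it falls strictly
outside its healthy interval — the boundaries themselves count as healthy —
and 0 otherwise.  Qualitative variables are labelled by benign-set membership:
rural environment and the "no associated pathology" category are 0, urban and
every disease category are 1, and the remaining qualitative variables follow
the benign sets declared in the schema.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CohortSchema, CohortTable, SchemaError, VariableSpec


@dataclass(frozen=True)
class LabelMatrix:
    """n_records x n_variables matrix of 0/1 labels."""

    values: np.ndarray
    record_ids: tuple[str, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2 or v.shape != (len(self.record_ids), len(self.names)):
            raise ValueError("label matrix shape must be n_records x n_variables")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.record_ids),
                            columns=list(self.names))


def label_value(value, spec: VariableSpec) -> int:
    """Label one value: 1 iff outside the (closed) healthy interval / non-benign."""
    if spec.is_numeric:
        v = float(value)
        return int(v < spec.healthy_lo or v > spec.healthy_hi)
    if value not in spec.categories:
        raise SchemaError(f"{spec.name}: unknown category {value!r}")
    return int(value not in spec.benign_categories)


def label_cohort(table: CohortTable) -> LabelMatrix:
    """Element-wise labelling of every record (reference rows excluded)."""
    schema = table.schema
    values = np.zeros((table.n_records, len(schema)), dtype=np.int8)
    for j, spec in enumerate(schema):
        col = table.records[spec.name].to_numpy()
        if spec.is_numeric:
            v = col.astype(float)
            values[:, j] = (v < spec.healthy_lo) | (v > spec.healthy_hi)
        else:
            bad = sorted(set(col) - set(spec.categories))
            if bad:
                raise SchemaError(f"{spec.name}: unknown category label(s) {bad}")
            values[:, j] = ~np.isin(col, list(spec.benign_categories))
    return LabelMatrix(values=values, record_ids=tuple(table.record_ids),
                       names=tuple(schema.names))
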