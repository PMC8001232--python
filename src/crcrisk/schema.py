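"""Cohort schema and table I/O.

A cohort is a patient-by-variable table whose first two data rows hold the
healthy-range minimum and maximum of every column (the layout clinicians use
when a lab report prints reference intervals next to results).  The schema
declares, per variable, the healthy interval plus the plausible extreme bounds
that delimit the "unhealthy" flanks used by the deviation weights and by the
worst-case normalization, or — for qualitative variables — the category set
and which categories count as benign.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

NUMERIC = "numeric"
QUALITATIVE = "qualitative"

#: Width of the full cohort contract: 33 analytes + 12 qualitative variables.
FULL_SCHEMA_WIDTH = 45
FULL_NUMERIC_COUNT = 33

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A variable or schema definition violates its invariants."""


class CohortFormatError(ValueError):
    """A cohort file does not conform to the schema/table contract."""


@dataclass(frozen=True)
class VariableSpec:
    """One clinical variable: healthy interval, extremes, or category sets.

    For numeric variables ``extreme_lo <= healthy_lo < healthy_hi <= extreme_hi``
    must hold; a variable whose healthy minimum is 0 may not have a lower
    unhealthy flank (the below-range deviation divides by ``healthy_lo``).
    """

    name: str
    kind: str
    healthy_lo: float | None = None
    healthy_hi: float | None = None
    extreme_lo: float | None = None
    extreme_hi: float | None = None
    unit: str | None = None
    categories: tuple[str, ...] = ()
    benign_categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, QUALITATIVE):
            raise SchemaError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == NUMERIC:
            bounds = (self.extreme_lo, self.healthy_lo, self.healthy_hi, self.extreme_hi)
            if any(b is None for b in bounds):
                raise SchemaError(f"{self.name}: numeric variable must supply all four bounds")
            elo, lo, hi, ehi = (float(b) for b in bounds)  # type: ignore[arg-type]
            if not (elo <= lo < hi <= ehi):
                raise SchemaError(
                    f"{self.name}: bounds must satisfy extreme_lo <= healthy_lo < "
                    f"healthy_hi <= extreme_hi, got [{elo}, {lo}, {hi}, {ehi}]"
                )
            if lo == 0.0 and elo < lo:
                raise SchemaError(
                    f"{self.name}: healthy_lo is 0 but the variable can deviate below "
                    "(below-range deviation would divide by zero)"
                )
        else:
            if not self.categories:
                raise SchemaError(f"{self.name}: qualitative variable needs categories")
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"{self.name}: duplicate categories")
            unknown = set(self.benign_categories) - set(self.categories)
            if unknown:
                raise SchemaError(f"{self.name}: benign categories {sorted(unknown)} not in categories")
            if not self.benign_categories:
                raise SchemaError(f"{self.name}: qualitative variable needs benign categories")

    @property
    def is_numeric(self) -> bool:
        return self.kind == NUMERIC

    def category_code(self, category: str) -> int:
        """1-based integer code of a category (its position in the declared order)."""
        try:
            return self.categories.index(category) + 1
        except ValueError:
            raise SchemaError(f"{self.name}: unknown category {category!r}") from None


@dataclass(frozen=True)
class CohortSchema:
    """Ordered collection of variable specs with unique names."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dupes}")
        if not self.variables:
            raise SchemaError("schema has no variables")

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def numeric(self) -> list[VariableSpec]:
        return [v for v in self.variables if v.is_numeric]

    @property
    def qualitative(self) -> list[VariableSpec]:
        return [v for v in self.variables if not v.is_numeric]

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass
class CohortTable:
    """Patient records plus the two leading reference-range rows.

    ``records`` is a DataFrame indexed by record id; numeric columns are
    float64, qualitative columns hold category labels.  ``reference_rows`` is a
    2 x n_variables array (healthy minima; healthy maxima) with NaN in
    qualitative columns.
    """

    schema: CohortSchema
    records: pd.DataFrame
    reference_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.records.columns) != self.schema.names:
            raise CohortFormatError(
                f"record columns {list(self.records.columns)} do not match schema "
                f"({len(self.schema)} variables)"
            )
        if self.reference_rows is None:
            self.reference_rows = reference_rows_for(self.schema)
        self.reference_rows = np.asarray(self.reference_rows, dtype=float)
        if self.reference_rows.shape != (2, len(self.schema)):
            raise CohortFormatError(
                f"reference rows must be 2 x {len(self.schema)}, got {self.reference_rows.shape}"
            )
        for j, spec in enumerate(self.schema):
            if spec.is_numeric:
                lo, hi = self.reference_rows[0, j], self.reference_rows[1, j]
                if not (np.isclose(lo, spec.healthy_lo) and np.isclose(hi, spec.healthy_hi)):
                    raise CohortFormatError(
                        f"{spec.name}: reference rows [{lo}, {hi}] disagree with schema "
                        f"healthy range [{spec.healthy_lo}, {spec.healthy_hi}]"
                    )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [str(i) for i in self.records.index]

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.schema == other.schema
            and np.allclose(self.reference_rows, other.reference_rows, equal_nan=True)
            and self.records.shape == other.records.shape
            and list(self.records.index) == list(other.records.index)
            and all(
                np.allclose(self.records[c], other.records[c])
                if self.schema[c].is_numeric
                else (self.records[c] == other.records[c]).all()
                for c in self.records.columns
            )
        )


def reference_rows_for(schema: CohortSchema) -> np.ndarray:
    """Healthy min/max rows implied by a schema (NaN for qualitative columns)."""
    rows = np.full((2, len(schema)), np.nan)
    for j, spec in enumerate(schema):
        if spec.is_numeric:
            rows[0, j] = spec.healthy_lo
            rows[1, j] = spec.healthy_hi
    return rows


def _parse_variable(block: dict) -> VariableSpec:
    if "name" not in block:
        raise SchemaError(f"variable block without a name: {block}")
    name = str(block["name"])
    kind = block.get("kind")
    if kind == NUMERIC:
        healthy = block.get("healthy")
        extreme = block.get("extreme")
        if not (isinstance(healthy, (list, tuple)) and len(healthy) == 2):
            raise SchemaError(f"{name}: numeric variable must supply healthy: [lo, hi]")
        if not (isinstance(extreme, (list, tuple)) and len(extreme) == 2):
            raise SchemaError(f"{name}: numeric variable must supply extreme: [lo, hi]")
        return VariableSpec(
            name=name,
            kind=NUMERIC,
            healthy_lo=float(healthy[0]),
            healthy_hi=float(healthy[1]),
            extreme_lo=float(extreme[0]),
            extreme_hi=float(extreme[1]),
            unit=block.get("unit"),
        )
    if kind == QUALITATIVE:
        return VariableSpec(
            name=name,
            kind=QUALITATIVE,
            categories=tuple(str(c) for c in block.get("categories", ())),
            benign_categories=tuple(str(c) for c in block.get("benign", ())),
        )
    raise SchemaError(f"{name}: unknown kind {kind!r}")


def load_schema(path: str | Path | None = None) -> CohortSchema:
    """Load and validate a 45-variable schema from YAML (default: bundled).

    The full-cohort contract (exactly 45 variables) is enforced here; toy
    schemas for experimentation can be built directly via :class:`CohortSchema`.
    """
    if path is None:
        text = resources.files("crcrisk.data").joinpath("default_schema.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise SchemaError("schema file must contain a top-level 'variables' list")
    schema = CohortSchema(tuple(_parse_variable(b) for b in doc["variables"]))
    if len(schema) != FULL_SCHEMA_WIDTH:
        raise SchemaError(
            f"cohort schema must declare exactly {FULL_SCHEMA_WIDTH} variables, got {len(schema)}"
        )
    return schema


def default_schema() -> CohortSchema:
    return load_schema(None)


def read_cohort(path: str | Path | io.TextIOBase, schema: CohortSchema) -> CohortTable:
    """Read a cohort CSV: header, healthy-min row, healthy-max row, patients."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] != len(schema) + 1 or df.columns[0] != "record_id":
        raise CohortFormatError(
            f"expected a record_id column followed by {len(schema)} variable columns, "
            f"got {df.shape[1]} columns"
        )
    if list(df.columns[1:]) != schema.names:
        raise CohortFormatError("variable columns do not match schema names/order")
    if len(df) < 2:
        raise CohortFormatError("cohort file must contain the two reference-range rows")

    ref = np.full((2, len(schema)), np.nan)
    for j, spec in enumerate(schema):
        if spec.is_numeric:
            for i in range(2):
                cell = df.iloc[i, j + 1]
                try:
                    ref[i, j] = float(cell)
                except ValueError:
                    raise CohortFormatError(
                        f"{spec.name}: non-numeric reference value {cell!r}"
                    ) from None

    body = df.iloc[2:]
    records = pd.DataFrame(index=pd.Index(body["record_id"].tolist(), name="record_id"))
    for spec in schema:
        col = body[spec.name]
        if spec.is_numeric:
            try:
                records[spec.name] = col.astype(float).to_numpy()
            except ValueError as exc:
                raise CohortFormatError(f"{spec.name}: non-numeric entry ({exc})") from None
        else:
            bad = sorted(set(col) - set(spec.categories))
            if bad:
                raise CohortFormatError(f"{spec.name}: unknown category label(s) {bad}")
            records[spec.name] = col.to_numpy()
    return CohortTable(schema=schema, records=records, reference_rows=ref)


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; ``read_cohort(write_cohort(t)) == t`` at 10 significant digits."""
    lines = [",".join(["record_id"] + table.schema.names)]
    for i, label in enumerate(("healthy_min", "healthy_max")):
        cells = [label]
        for j, spec in enumerate(table.schema):
            cells.append(_fmt(table.reference_rows[i, j]) if spec.is_numeric else "")
        lines.append(",".join(cells))
    for rid, row in table.records.iterrows():
        cells = [str(rid)]
        for spec in table.schema:
            v = row[spec.name]
            cells.append(_fmt(float(v)) if spec.is_numeric else str(v))
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
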