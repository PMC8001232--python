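"""Continuous cancer-probability score from reference-range deviations.

The score of a record is a weighted average of per-variable deviation
percentages, rescaled so that a fictive worst-case patient (every variable at
its maximal-deviation extreme) scores exactly 100%:

    d_i  = 0                                  if value inside [lo_i, hi_i]
         = 100 (value - hi_i) / hi_i          if value above the healthy range
         = 100 (lo_i - value) / lo_i          if value below the healthy range
    s    = sum_i w_i d_i                      with unit-sum weights w
    score = 100 * s / s_worst_case            in [0, 100]

Qualitative variables deviate 0 (benign category) or 100 (non-benign).  Three
weight constructions are provided: near-uniform "convergent" weights, weights
proportional to the mean relative deflection between the healthy boundaries
and the plausible extremes, and a "combined" scheme that keeps the deflection
ordering but compresses the raw values into the narrow band [0.01, 0.03]
before unit-sum rescaling.  A record is labelled positive when its normalized
score strictly exceeds the 50% threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CohortSchema, CohortTable, SchemaError, VariableSpec

SCHEME_CONVERGENT = "convergent"
SCHEME_DEFLECTION = "deflection"
SCHEME_COMBINED = "combined"
SCHEMES = (SCHEME_CONVERGENT, SCHEME_DEFLECTION, SCHEME_COMBINED)

#: Band the convergent-scheme override values must lie in.
CONVERGENT_BAND = (0.015, 0.05)
#: Band the combined-scheme raw weights are mapped onto.
COMBINED_BAND = (0.01, 0.03)

DEFAULT_THRESHOLD = 50.0


@dataclass(frozen=True)
class WeightVector:
    """Unit-sum per-variable weights of risk."""

    scheme: str
    names: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.names):
            raise ValueError("weights must be one value per variable")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ScoreResult:
    raw: float
    normalized: float
    label: bool
    scheme: str
    threshold: float = DEFAULT_THRESHOLD


@dataclass(frozen=True)
class DeviationMatrix:
    """Per-record, per-variable deviation percentages (>= 0)."""

    values: np.ndarray
    record_ids: tuple[str, ...]
    names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.record_ids), columns=list(self.names))


def deviation_percent(value, spec: VariableSpec) -> float:
    """Deviation of one value from its healthy range, as a percentage of the
    violated healthy boundary (0 if in range; qualitative: 0 benign / 100 not)."""
    if spec.is_numeric:
        v = float(value)
        if v > spec.extreme_hi or v < spec.extreme_lo:
            raise ValueError(f"{spec.name}: value {v} outside extremes "
                             f"[{spec.extreme_lo}, {spec.extreme_hi}]")
        if v > spec.healthy_hi:
            return 100.0 * (v - spec.healthy_hi) / spec.healthy_hi
        if v < spec.healthy_lo:
            return 100.0 * (spec.healthy_lo - v) / spec.healthy_lo
        return 0.0
    if value not in spec.categories:
        raise SchemaError(f"{spec.name}: unknown category {value!r}")
    return 0.0 if value in spec.benign_categories else 100.0


def max_deviations(spec: VariableSpec) -> tuple[float, float]:
    """(below, above) maximal attainable deviation percentages of a variable."""
    if not spec.is_numeric:
        return (100.0, 100.0)
    below = 0.0
    if spec.extreme_lo < spec.healthy_lo:
        below = 100.0 * (spec.healthy_lo - spec.extreme_lo) / spec.healthy_lo
    above = 0.0
    if spec.extreme_hi > spec.healthy_hi:
        above = 100.0 * (spec.extreme_hi - spec.healthy_hi) / spec.healthy_hi
    return below, above


def max_deviation(spec: VariableSpec) -> float:
    return max(max_deviations(spec))


def worst_case_side(spec: VariableSpec) -> str:
    """Which extreme ('lo' or 'hi') yields the larger deviation (ties -> 'hi')."""
    below, above = max_deviations(spec)
    return "hi" if above >= below else "lo"


def _unit_sum(scheme: str, names, raw: np.ndarray) -> WeightVector:
    raw = np.asarray(raw, dtype=float)
    return WeightVector(scheme=scheme, names=tuple(names), weights=raw / raw.sum())


def weights_convergent(schema: CohortSchema, overrides: dict[str, float] | None = None) -> WeightVector:
    """Near-uniform weights: 1/n each, or user values in [0.015, 0.05] rescaled."""
    n = len(schema)
    raw = np.full(n, 1.0 / n)
    if overrides:
        unknown = set(overrides) - set(schema.names)
        if unknown:
            raise SchemaError(f"override for unknown variable(s): {sorted(unknown)}")
        lo, hi = CONVERGENT_BAND
        for name, value in overrides.items():
            if value <= 0:
                raise ValueError(f"{name}: weight override must be positive, got {value}")
            if not (lo <= value <= hi):
                raise ValueError(f"{name}: override {value} outside the convergent band [{lo}, {hi}]")
            raw[schema.names.index(name)] = value
    return _unit_sum(SCHEME_CONVERGENT, schema.names, raw)


def deflection_raw_weights(schema: CohortSchema) -> np.ndarray:
    """Per-variable mean relative deflection between healthy bounds and extremes.

    Numeric: mean of (lo - extreme_lo)/lo and (extreme_hi - hi)/hi.
    Qualitative: 1 (full-deflection convention; their deviation is 0 or 100%).
    """
    raw = np.empty(len(schema))
    for j, spec in enumerate(schema):
        if spec.is_numeric:
            below, above = max_deviations(spec)
            raw[j] = 0.5 * (below + above) / 100.0
        else:
            raw[j] = 1.0
    if np.any(raw <= 0):
        bad = [schema.names[j] for j in np.flatnonzero(raw <= 0)]
        raise SchemaError(f"variables with no deflection range: {bad}")
    return raw


def weights_deflection(schema: CohortSchema) -> WeightVector:
    return _unit_sum(SCHEME_DEFLECTION, schema.names, deflection_raw_weights(schema))


def weights_combined(schema: CohortSchema) -> WeightVector:
    """Deflection-ordered weights compressed into the band [0.01, 0.03].

    The raw deflection weights are mapped affinely (min -> 0.01, max -> 0.03)
    so every variable keeps its importance rank while no variable dominates;
    if all raw weights coincide the map degenerates to the band midpoint.
    """
    raw = deflection_raw_weights(schema)
    lo, hi = COMBINED_BAND
    span = raw.max() - raw.min()
    if span == 0.0:
        banded = np.full_like(raw, 0.5 * (lo + hi))
    else:
        banded = lo + (raw - raw.min()) * (hi - lo) / span
    return _unit_sum(SCHEME_COMBINED, schema.names, banded)


def make_weights(schema: CohortSchema, scheme: str,
                 overrides: dict[str, float] | None = None) -> WeightVector:
    if scheme == SCHEME_CONVERGENT:
        return weights_convergent(schema, overrides)
    if scheme == SCHEME_DEFLECTION:
        return weights_deflection(schema)
    if scheme == SCHEME_COMBINED:
        return weights_combined(schema)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def raw_score(deviations, weights: WeightVector) -> float:
    """Weighted average of deviation percentages: sum_i w_i d_i."""
    d = np.asarray(deviations, dtype=float)
    if d.shape != (len(weights),):
        raise ValueError(f"expected {len(weights)} deviations, got shape {d.shape}")
    return float(d @ weights.weights)


def worst_case_deviations(schema: CohortSchema) -> np.ndarray:
    return np.array([max_deviation(spec) for spec in schema])


def worst_case_score(schema: CohortSchema, weights: WeightVector) -> float:
    """Score of the fictive 100%-cancer patient; the normalization denominator."""
    wc = raw_score(worst_case_deviations(schema), weights)
    if wc <= 0:
        raise SchemaError("worst-case score is not positive; schema has no deviation room")
    return wc


def record_deviations(record, schema: CohortSchema) -> np.ndarray:
    return np.array([deviation_percent(record[spec.name], spec) for spec in schema])


def normalized_score(record, schema: CohortSchema, weights: WeightVector,
                     threshold: float = DEFAULT_THRESHOLD) -> ScoreResult:
    """Score one record; the label is positive iff the score strictly exceeds
    the threshold (a record at exactly 50% stays negative)."""
    raw = raw_score(record_deviations(record, schema), weights)
    norm = 100.0 * raw / worst_case_score(schema, weights)
    return ScoreResult(raw=raw, normalized=norm, label=bool(norm > threshold),
                       scheme=weights.scheme, threshold=threshold)


def deviation_matrix(table: CohortTable) -> DeviationMatrix:
    schema = table.schema
    n = table.n_records
    values = np.zeros((n, len(schema)))
    for j, spec in enumerate(schema):
        col = table.records[spec.name].to_numpy()
        if spec.is_numeric:
            v = col.astype(float)
            above = v > spec.healthy_hi
            below = v < spec.healthy_lo
            values[above, j] = 100.0 * (v[above] - spec.healthy_hi) / spec.healthy_hi
            values[below, j] = 100.0 * (spec.healthy_lo - v[below]) / spec.healthy_lo
        else:
            benign = np.isin(col, list(spec.benign_categories))
            values[~benign, j] = 100.0
    return DeviationMatrix(values=values, record_ids=tuple(table.record_ids),
                           names=tuple(schema.names))


def score_cohort(table: CohortTable, weights: WeightVector,
                 threshold: float = DEFAULT_THRESHOLD) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scoring: (continuous 0-100 scores, binary labels) per record.

    The continuous vector is the regression response; the binary vector is the
    classification response.
    """
    dev = deviation_matrix(table).values
    wc = worst_case_score(table.schema, weights)
    continuous = 100.0 * (dev @ weights.weights) / wc
    return continuous, (continuous > threshold).astype(np.int8)


def score_frame(table: CohortTable, weights: WeightVector,
                threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-record score report: record_id, raw, normalized, label, scheme."""
    dev = deviation_matrix(table).values
    raw = dev @ weights.weights
    wc = worst_case_score(table.schema, weights)
    norm = 100.0 * raw / wc
    return pd.DataFrame(
        {
            "record_id": table.record_ids,
            "raw": raw,
            "normalized": norm,
            "label": (norm > threshold).astype(int),
            "scheme": weights.scheme,
        }
    ).set_index("record_id")
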