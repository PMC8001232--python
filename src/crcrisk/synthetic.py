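"""Seeded synthetic cohort generation.

The generator emulates the statistical structure the downstream analysis
assumes: a base cohort of 200 patients expanded to 900 records by
resample-and-jitter augmentation, with roughly 65% of records scoring above
the 50% risk threshold.  Records are drawn from a two-component mixture: a
high-burden ("case-like") component whose out-of-range values sit close to
the plausible extremes, and a low-burden component with few, mild
abnormalities.  Within the healthy range values follow a truncated
bell-shaped distribution; out-of-range values follow a truncated exponential
law over the unhealthy flank — decaying away from the violated boundary for
the mild component and away from the extreme for the severe one.

The defaults define the emulated study conditions; they are parameters, not
fits to any real cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .schema import CohortSchema, CohortTable, SchemaError, VariableSpec
from .scoring import max_deviations, worst_case_side


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort parameters.

    ``abnormality_burden`` is the expected fraction of out-of-range variables
    per record.  Left at ``None`` it resolves to the mixture mean of the two
    component burdens; setting it explicitly switches the generator to a
    homogeneous cohort in which every record carries that burden (useful for
    degenerate checks: burden 0 keeps every value in range, burden 1 pushes
    every value out).
    """

    n_base: int = 200
    n_total: int = 900
    abnormality_burden: float | None = None
    positive_prevalence_target: float = 0.649
    jitter_fraction: float = 0.02
    seed: int = 0
    # mixture-component sampling profile
    healthy_burden: float = 0.075
    sick_burden: float = 0.95
    burden_concentration: float = 60.0
    healthy_flank_scale: float = 0.15
    sick_flank_scale: float = 0.1
    severe_side_prob_healthy: float = 0.5
    severe_side_prob_sick: float = 0.97

    def __post_init__(self) -> None:
        if self.n_total < self.n_base:
            raise ValueError(f"n_total ({self.n_total}) must be >= n_base ({self.n_base})")
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        for name in ("positive_prevalence_target", "jitter_fraction",
                     "healthy_burden", "sick_burden",
                     "severe_side_prob_healthy", "severe_side_prob_sick"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.abnormality_burden is not None and not (0.0 <= self.abnormality_burden <= 1.0):
            raise ValueError("abnormality_burden must lie in [0, 1]")

    @property
    def component_burdens(self) -> tuple[float, float]:
        """(healthy-component, sick-component) mean burdens after resolution."""
        if self.abnormality_burden is None:
            return self.healthy_burden, self.sick_burden
        return self.abnormality_burden, self.abnormality_burden

    @property
    def expected_burden(self) -> float:
        """Cohort-level expected fraction of out-of-range variables."""
        b_h, b_s = self.component_burdens
        p = self.positive_prevalence_target
        return p * b_s + (1.0 - p) * b_h


def _record_burdens(rng: np.random.Generator, mean: np.ndarray, kappa: float) -> np.ndarray:
    """Per-record burden draws: Beta(mean*k, (1-mean)*k), degenerate at 0/1."""
    mean = np.asarray(mean, dtype=float)
    out = mean.copy()
    mid = (mean > 0.0) & (mean < 1.0)
    if kappa > 0 and mid.any():
        out[mid] = rng.beta(mean[mid] * kappa, (1.0 - mean[mid]) * kappa)
    return out


def _trunc_exp(u: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Inverse-CDF of an exponential truncated to [0, 1]; scale 0 -> point mass 0."""
    f = np.zeros_like(u)
    pos = scale > 0
    s = scale[pos]
    f[pos] = -s * np.log1p(-u[pos] * (1.0 - np.exp(-1.0 / s)))
    return f


def sample_base_cohort(schema: CohortSchema, config: GeneratorConfig) -> CohortTable:
    """Draw the base cohort (``n_base`` records); identical seed, identical table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_base
    b_h, b_s = config.component_burdens

    # exact case allocation: round(p*n) case-like records in shuffled order
    n_sick = int(round(config.positive_prevalence_target * n))
    sick = np.zeros(n, dtype=bool)
    sick[rng.permutation(n)[:n_sick]] = True
    burden = _record_burdens(rng, np.where(sick, b_s, b_h), config.burden_concentration)
    flank_scale = np.where(sick, config.sick_flank_scale, config.healthy_flank_scale)
    severe_prob = np.where(sick, config.severe_side_prob_sick, config.severe_side_prob_healthy)

    columns: dict[str, np.ndarray] = {}
    for spec in schema:
        if spec.is_numeric:
            columns[spec.name] = _sample_numeric(rng, spec, n, burden, sick,
                                                 flank_scale, severe_prob)
        else:
            columns[spec.name] = _sample_qualitative(rng, spec, n, burden)

    ids = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="record_id")
    return CohortTable(schema=schema, records=pd.DataFrame(columns, index=ids))


def _sample_numeric(rng, spec: VariableSpec, n, burden, sick, flank_scale, severe_prob):
    lo, hi = spec.healthy_lo, spec.healthy_hi
    mid, sd = 0.5 * (lo + hi), (hi - lo) / 6.0
    a, b = (lo - mid) / sd, (hi - mid) / sd
    values = truncnorm.rvs(a, b, loc=mid, scale=sd, size=n, random_state=rng)

    out = rng.random(n) < burden
    below_ok = spec.extreme_lo < lo
    above_ok = spec.extreme_hi > hi
    if not (below_ok or above_ok):
        return values  # no unhealthy flank: the variable cannot leave its range

    below_max, above_max = max_deviations(spec)
    take_severe = rng.random(n) < severe_prob
    if not below_ok:
        go_above = np.ones(n, dtype=bool)
    elif not above_ok:
        go_above = np.zeros(n, dtype=bool)
    elif above_max >= below_max:
        go_above = take_severe
    else:
        go_above = ~take_severe

    f = _trunc_exp(rng.random(n), flank_scale)
    f = np.where(sick, 1.0 - f, f)  # severe component: mass near the extreme
    v_out = np.where(go_above,
                     hi + f * (spec.extreme_hi - hi),
                     lo - f * (lo - spec.extreme_lo))
    values[out] = v_out[out]
    return values


def _sample_qualitative(rng, spec: VariableSpec, n, burden):
    benign = list(spec.benign_categories)
    non_benign = [c for c in spec.categories if c not in spec.benign_categories]
    pick_benign = rng.integers(0, len(benign), n)
    col = np.array(benign, dtype=object)[pick_benign]
    if non_benign:
        abnormal = rng.random(n) < burden
        pick_bad = rng.integers(0, len(non_benign), n)
        col[abnormal] = np.array(non_benign, dtype=object)[pick_bad[abnormal]]
    return col


def augment_cohort(base: CohortTable, config: GeneratorConfig) -> CohortTable:
    """Expand the base cohort to ``n_total`` records.

    Extra records are resampled with replacement from the base and perturbed
    by zero-mean Gaussian noise with scale ``jitter_fraction`` x healthy-range
    width per numeric variable, clipped to the extremes; qualitative values
    are copied unchanged.
    """
    if base.n_records < 1:
        raise ValueError("base cohort must contain at least one record")
    if config.n_total < base.n_records:
        raise ValueError(f"n_total ({config.n_total}) is smaller than the base "
                         f"cohort ({base.n_records})")
    n_extra = config.n_total - base.n_records
    rng = np.random.default_rng([config.seed, 0xA6])
    src = rng.integers(0, base.n_records, n_extra)

    extra: dict[str, np.ndarray] = {}
    for spec in base.schema:
        col = base.records[spec.name].to_numpy()
        if spec.is_numeric:
            width = spec.healthy_hi - spec.healthy_lo
            noise = rng.normal(0.0, config.jitter_fraction * width, n_extra) \
                if config.jitter_fraction > 0 else np.zeros(n_extra)
            extra[spec.name] = np.clip(col[src].astype(float) + noise,
                                       spec.extreme_lo, spec.extreme_hi)
        else:
            extra[spec.name] = col[src]

    base_ids = list(base.records.index)
    extra_ids = [f"{base_ids[s]}~a{k + 1}" for k, s in enumerate(src)]
    records = pd.concat([
        base.records,
        pd.DataFrame(extra, index=pd.Index(extra_ids, name="record_id")),
    ])
    return CohortTable(schema=base.schema, records=records,
                       reference_rows=base.reference_rows)


def generate_cohort(schema: CohortSchema, config: GeneratorConfig) -> CohortTable:
    """Base sampling followed by augmentation: the full synthetic cohort."""
    return augment_cohort(sample_base_cohort(schema, config), config)


def make_healthy_patient(schema: CohortSchema) -> pd.Series:
    """Record with every numeric value at the healthy midpoint and every
    qualitative value benign; its labels are all 0 and its risk score is 0."""
    values = {}
    for spec in schema:
        if spec.is_numeric:
            values[spec.name] = 0.5 * (spec.healthy_lo + spec.healthy_hi)
        else:
            values[spec.name] = spec.benign_categories[0]
    return pd.Series(values, name="healthy")


def make_worst_case_patient(schema: CohortSchema) -> pd.Series:
    """Fictive 100%-cancer record: every numeric value at the extreme with the
    larger deviation percentage, every qualitative value non-benign."""
    values = {}
    for spec in schema:
        if spec.is_numeric:
            values[spec.name] = (spec.extreme_hi if worst_case_side(spec) == "hi"
                                 else spec.extreme_lo)
        else:
            non_benign = [c for c in spec.categories if c not in spec.benign_categories]
            if not non_benign:
                raise SchemaError(f"{spec.name}: no non-benign category for the worst case")
            values[spec.name] = non_benign[0]
    return pd.Series(values, name="worst_case")
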