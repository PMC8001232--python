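"""Risk-score arithmetic: deviations, weight schemes, normalization, oracle."""
import numpy as np
import pandas as pd
import pytest

from conftest import random_record, random_toy_schema, toy_numeric, toy_qualitative
from crcrisk import (
    CohortSchema,
    GeneratorConfig,
    generate_cohort,
    make_healthy_patient,
    make_weights,
    make_worst_case_patient,
    normalized_score,
    raw_score,
    score_cohort,
    weights_combined,
    weights_convergent,
    weights_deflection,
    worst_case_score,
)
from crcrisk.schema import CohortTable
from crcrisk.scoring import SCHEMES, deviation_percent, deflection_raw_weights


# ---------------------------------------------------------------- brute-force
# Independent oracle: direct, loop-based recomputation of the whole scoring
# path (deviations -> weights -> worst case -> normalization), kept free of
# the library's vectorized implementation.

def oracle_deviation(value, spec):
    if spec.kind == "qualitative":
        return 0.0 if value in spec.benign_categories else 100.0
    v = float(value)
    if v > spec.healthy_hi:
        return 100.0 * (v - spec.healthy_hi) / spec.healthy_hi
    if v < spec.healthy_lo:
        return 100.0 * (spec.healthy_lo - v) / spec.healthy_lo
    return 0.0


def oracle_weights(schema, scheme):
    raws = []
    for spec in schema:
        if spec.kind == "qualitative":
            raws.append(1.0)
        else:
            below = (spec.healthy_lo - spec.extreme_lo) / spec.healthy_lo
            above = (spec.extreme_hi - spec.healthy_hi) / spec.healthy_hi
            raws.append(0.5 * (below + above))
    if scheme == "convergent":
        raws = [1.0] * len(schema)
    elif scheme == "combined":
        lo, hi = min(raws), max(raws)
        if hi == lo:
            raws = [0.02] * len(schema)
        else:
            raws = [0.01 + (r - lo) * 0.02 / (hi - lo) for r in raws]
    total = sum(raws)
    return [r / total for r in raws]


def oracle_normalized(record, schema, scheme):
    w = oracle_weights(schema, scheme)
    raw = sum(wi * oracle_deviation(record[spec.name], spec)
              for wi, spec in zip(w, schema))
    worst = sum(
        wi * max(
            (spec.healthy_lo - spec.extreme_lo) / spec.healthy_lo * 100.0
            if spec.kind == "numeric" and spec.extreme_lo < spec.healthy_lo else 0.0,
            (spec.extreme_hi - spec.healthy_hi) / spec.healthy_hi * 100.0
            if spec.kind == "numeric" else 100.0,
        )
        for wi, spec in zip(w, schema)
    )
    return 100.0 * raw / worst


# ----------------------------------------------------------------- unit tests

class TestDeviationPercent:
    @pytest.mark.parametrize("value,expected", [
        (4.2, 0.0),        # in range
        (3.5, 0.0),        # boundary is healthy
        (5.0, 0.0),
        (7.5, 50.0),       # 100 * (7.5 - 5.0) / 5.0
        (1.75, 50.0),      # 100 * (3.5 - 1.75) / 3.5
        (15.0, 200.0),
        (0.0, 100.0),
    ])
    def test_numeric_deviation(self, toy_schema, value, expected):
        assert deviation_percent(value, toy_schema["a"]) == pytest.approx(expected)

    def test_qualitative_deviation_is_binary(self, toy_schema):
        q = toy_schema["q"]
        assert deviation_percent("ok", q) == 0.0
        assert deviation_percent("bad", q) == 100.0

    def test_value_outside_extremes_rejected(self, toy_schema):
        with pytest.raises(ValueError):
            deviation_percent(16.0, toy_schema["a"])


class TestWeightSchemes:
    def test_convergent_default_uniform(self, schema):
        w = weights_convergent(schema)
        assert np.allclose(w.weights, 1.0 / 45.0)
        assert abs(w.weights.sum() - 1.0) < 1e-9

    def test_convergent_overrides_rescaled_order_preserving(self, schema):
        overrides = {"albumin": 0.05, "glycemia": 0.015}
        w = weights_convergent(schema, overrides)
        assert abs(w.weights.sum() - 1.0) < 1e-9
        i, j = schema.names.index("albumin"), schema.names.index("glycemia")
        assert w.weights[i] > w.weights[j]

    @pytest.mark.parametrize("bad", [-0.02, 0.0, 0.2])
    def test_convergent_rejects_out_of_band_overrides(self, schema, bad):
        with pytest.raises(ValueError):
            weights_convergent(schema, {"albumin": bad})

    def test_deflection_raw_weight_hand_arithmetic(self, toy_schema):
        # healthy [3.5, 5.0], extremes [0, 15] -> mean of 1.0 and 2.0 = 1.5
        raws = deflection_raw_weights(toy_schema)
        assert raws[0] == pytest.approx(1.5)
        assert raws[1] == pytest.approx(1.0)   # mean of 1.0 and 1.0
        assert raws[2] == 1.0                  # qualitative convention

    def test_deflection_uniform_when_raws_identical(self):
        schema = CohortSchema(tuple(
            toy_numeric(f"v{i}", (1.0, 2.0), (0.0, 4.0)) for i in range(4)))
        w = weights_deflection(schema)
        assert np.allclose(w.weights, 0.25)

    def test_deflection_grows_with_extreme(self):
        base = CohortSchema((toy_numeric("a", (1.0, 2.0), (0.0, 4.0)),
                             toy_numeric("b", (1.0, 2.0), (0.0, 4.0))))
        wider = CohortSchema((toy_numeric("a", (1.0, 2.0), (0.0, 8.0)),
                              toy_numeric("b", (1.0, 2.0), (0.0, 4.0))))
        assert (weights_deflection(wider).weights[0]
                > weights_deflection(base).weights[0])

    def test_combined_affine_map_on_three_raws(self):
        # deflection raws {1.0, 1.5, 2.0} -> band values {0.01, 0.02, 0.03}
        schema = CohortSchema((
            toy_numeric("a", (1.0, 2.0), (0.0, 4.0)),   # raw 1.0
            toy_numeric("b", (1.0, 2.0), (0.0, 6.0)),   # raw 1.5
            toy_numeric("c", (1.0, 2.0), (0.0, 8.0)),   # raw 2.0
        ))
        w = weights_combined(schema)
        assert np.allclose(w.weights, np.array([0.01, 0.02, 0.03]) / 0.06)

    def test_combined_degenerate_maps_to_midpoint(self):
        schema = CohortSchema(tuple(
            toy_numeric(f"v{i}", (1.0, 2.0), (0.0, 4.0)) for i in range(3)))
        assert np.allclose(weights_combined(schema).weights, 1.0 / 3.0)

    def test_combined_preserves_deflection_rank_order(self, schema):
        raws = deflection_raw_weights(schema)
        combined = weights_combined(schema).weights
        # strictly increasing raw -> strictly increasing combined; ties stay tied
        order = np.argsort(raws)
        sr, sc = raws[order], combined[order]
        for i in range(len(sr) - 1):
            if sr[i] < sr[i + 1]:
                assert sc[i] < sc[i + 1]
            else:
                assert sc[i] == pytest.approx(sc[i + 1])

    def test_all_schemes_unit_sum(self, schema):
        for scheme in SCHEMES:
            assert abs(make_weights(schema, scheme).weights.sum() - 1.0) < 1e-9


class TestRawAndWorstCase:
    def test_weighted_average_toy(self):
        schema = CohortSchema((toy_numeric("a", (3.5, 5.0), (0.0, 15.0)),
                               toy_numeric("b", (1.0, 2.0), (0.0, 4.0))))
        w = weights_convergent(schema)  # (0.5, 0.5)
        assert raw_score([50.0, 0.0], w) == pytest.approx(25.0)
        assert raw_score([0.0, 0.0], w) == 0.0
        assert raw_score([30.0, 30.0], w) == pytest.approx(30.0)

    def test_worst_case_toy_150(self):
        # max deviations (200, 100), uniform weights -> 150
        schema = CohortSchema((toy_numeric("a", (3.5, 5.0), (0.0, 15.0)),
                               toy_numeric("b", (1.0, 2.0), (0.0, 4.0))))
        assert worst_case_score(schema, weights_convergent(schema)) == pytest.approx(150.0)

    def test_qualitative_only_schema_worst_case_100(self):
        schema = CohortSchema((toy_qualitative("q1"), toy_qualitative("q2")))
        assert worst_case_score(schema, weights_convergent(schema)) == pytest.approx(100.0)

    def test_worst_case_dominates_random_records(self, schema):
        rng = np.random.default_rng(3)
        for scheme in SCHEMES:
            w = make_weights(schema, scheme)
            wc = worst_case_score(schema, w)
            for _ in range(25):
                record = pd.Series(random_record(rng, schema))
                assert normalized_score(record, schema, w).raw <= wc + 1e-9


class TestNormalizedScore:
    def test_healthy_zero_worst_hundred_all_schemes(self, schema):
        hp, wc = make_healthy_patient(schema), make_worst_case_patient(schema)
        for scheme in SCHEMES:
            w = make_weights(schema, scheme)
            assert normalized_score(hp, schema, w).normalized == 0.0
            assert normalized_score(wc, schema, w).normalized == pytest.approx(100.0)

    def test_tie_at_threshold_is_negative(self):
        # one variable, deviation exactly half the worst case
        schema = CohortSchema((toy_numeric("a", (1.0, 2.0), (0.0, 4.0)),))
        w = weights_convergent(schema)
        record = pd.Series({"a": 3.0})  # deviation 50, worst case 100
        result = normalized_score(record, schema, w)
        assert result.normalized == pytest.approx(50.0)
        assert result.label is False
        assert normalized_score(pd.Series({"a": 3.1}), schema, w).label is True

    def test_monotone_in_single_deviation(self, schema):
        w = make_weights(schema, "combined")
        record = make_healthy_patient(schema)
        spec = schema["glycemia"]
        scores = [normalized_score(record.copy(), schema, w).normalized]
        for value in np.linspace(spec.healthy_hi, spec.extreme_hi, 8)[1:]:
            r = record.copy()
            r["glycemia"] = value
            scores.append(normalized_score(r, schema, w).normalized)
        assert (np.diff(scores) >= -1e-12).all()
        assert scores[-1] > scores[0]

    def test_scheme_equivalence_on_degenerate_schema(self):
        """Identical ranges/extremes everywhere -> all three schemes agree."""
        schema = CohortSchema(tuple(
            toy_numeric(f"v{i}", (1.0, 2.0), (0.5, 4.0)) for i in range(5)))
        rng = np.random.default_rng(11)
        for _ in range(10):
            record = pd.Series(random_record(rng, schema))
            scores = [normalized_score(record, schema, make_weights(schema, s)).normalized
                      for s in SCHEMES]
            assert np.ptp(scores) < 1e-9


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_toy_schemas(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            schema = random_toy_schema(rng)
            record = pd.Series(random_record(rng, schema))
            for scheme in SCHEMES:
                w = make_weights(schema, scheme)
                got = normalized_score(record, schema, w).normalized
                want = oracle_normalized(record, schema, scheme)
                assert got == pytest.approx(want, abs=1e-12)


class TestScoreCohort:
    def test_scores_in_unit_interval(self, schema, cohort):
        for scheme in SCHEMES:
            continuous, binary = score_cohort(cohort, make_weights(schema, scheme))
            assert continuous.shape == (900,)
            assert (continuous >= 0).all() and (continuous <= 100).all()
            assert ((binary == 0) | (binary == 1)).all()

    def test_combined_lies_between_other_schemes_mostly(self, schema, cohort):
        by_scheme = {s: score_cohort(cohort, make_weights(schema, s))[0] for s in SCHEMES}
        lo = np.minimum(by_scheme["convergent"], by_scheme["deflection"])
        hi = np.maximum(by_scheme["convergent"], by_scheme["deflection"])
        between = ((by_scheme["combined"] >= lo - 1e-9)
                   & (by_scheme["combined"] <= hi + 1e-9)).mean()
        assert between >= 0.90

    def test_default_cohort_prevalence_near_target(self, schema, cohort):
        for scheme in SCHEMES:
            _, binary = score_cohort(cohort, make_weights(schema, scheme))
            assert abs(binary.mean() - 0.649) <= 0.05

    def test_vectorized_matches_per_record(self, schema):
        table = generate_cohort(schema, GeneratorConfig(n_base=15, n_total=20, seed=9))
        w = make_weights(schema, "deflection")
        continuous, _ = score_cohort(table, w)
        for i, (_, record) in enumerate(table.records.iterrows()):
            assert continuous[i] == pytest.approx(
                normalized_score(record, schema, w).normalized, abs=1e-10)
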