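import numpy as np
import pytest

from crcrisk import CohortSchema, GeneratorConfig, VariableSpec, default_schema, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort(schema):
    """The default 900-record synthetic cohort at a fixed seed."""
    return generate_cohort(schema, GeneratorConfig(seed=20240))


def toy_numeric(name, healthy, extreme):
    return VariableSpec(name=name, kind="numeric",
                        healthy_lo=healthy[0], healthy_hi=healthy[1],
                        extreme_lo=extreme[0], extreme_hi=extreme[1])


def toy_qualitative(name, categories=("ok", "bad"), benign=("ok",)):
    return VariableSpec(name=name, kind="qualitative",
                        categories=tuple(categories), benign_categories=tuple(benign))


@pytest.fixture
def toy_schema():
    """Small mixed schema for hand-checkable arithmetic."""
    return CohortSchema((
        toy_numeric("a", (3.5, 5.0), (0.0, 15.0)),   # max deviations (100, 200)
        toy_numeric("b", (1.0, 2.0), (0.0, 4.0)),    # max deviations (100, 100)
        toy_qualitative("q"),
    ))


def random_toy_schema(rng: np.random.Generator, n_vars: int = 5) -> CohortSchema:
    """Random valid schema mixing numeric and qualitative variables."""
    specs = []
    for i in range(n_vars):
        if rng.random() < 0.75:
            lo = rng.uniform(0.5, 10.0)
            hi = lo + rng.uniform(0.5, 10.0)
            elo = lo - rng.uniform(0.0, lo)  # stays >= 0
            ehi = hi + rng.uniform(0.0, 5.0 * hi)
            specs.append(toy_numeric(f"v{i}", (lo, hi), (elo, ehi)))
        else:
            cats = tuple(f"c{j}" for j in range(int(rng.integers(2, 5))))
            n_benign = int(rng.integers(1, len(cats)))
            specs.append(toy_qualitative(f"v{i}", cats, cats[:n_benign]))
    return CohortSchema(tuple(specs))


def random_record(rng: np.random.Generator, schema: CohortSchema) -> dict:
    """Random record respecting the schema extremes."""
    record = {}
    for spec in schema:
        if spec.is_numeric:
            record[spec.name] = rng.uniform(spec.extreme_lo, spec.extreme_hi)
        else:
            record[spec.name] = spec.categories[rng.integers(0, len(spec.categories))]
    return record
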