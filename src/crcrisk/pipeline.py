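"""End-to-end pipeline: generate -> label -> score -> benches, with a manifest.

One master seed drives every stochastic stage through spawned child seeds, so
a rerun with the same configuration reproduces every numeric artifact
byte-for-byte (wall times excepted, which live only in the manifest's
informational section).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import classify, regress, scoring
from .labeling import label_cohort
from .schema import CohortSchema, load_schema, write_cohort
from .synthetic import GeneratorConfig, generate_cohort

log = logging.getLogger("crcrisk")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    schema_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scheme: str = scoring.SCHEME_COMBINED
    threshold: float = scoring.DEFAULT_THRESHOLD
    protocols: tuple[classify.ValidationProtocol, ...] = classify.STANDARD_PROTOCOLS
    roster_seedless: bool = False
    sweep: bool = True
    architectures: tuple[tuple[int, int], ...] = regress.SWEEP_ARCHITECTURES
    training: regress.TrainingConfig = field(default_factory=regress.TrainingConfig)
    seed: int = 0
    out_dir: str = "crcrisk_run"

    def config_hash(self) -> str:
        payload = json.dumps({
            "schema_path": self.schema_path,
            "generator": self.generator.__dict__,
            "scheme": self.scheme,
            "threshold": self.threshold,
            "protocols": [p.name for p in self.protocols],
            "sweep": self.sweep,
            "architectures": list(self.architectures),
            "training": self.training.__dict__,
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - abort naming the stage
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    seed_gen = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    seed_bench = int(seeds[1].generate_state(1)[0] % (2 ** 31))
    seed_sweep = int(seeds[2].generate_state(1)[0] % (2 ** 31))

    files: dict[str, Path] = {}
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}

    def timed(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s: %.2fs", name, timings[name])
        return result

    schema: CohortSchema = timed("schema", lambda: load_schema(config.schema_path))

    gen_cfg = replace(config.generator, seed=seed_gen)
    table = timed("generate", lambda: generate_cohort(schema, gen_cfg))
    counts["records"] = table.n_records
    files["cohort"] = out / "cohort.csv"
    write_cohort(table, files["cohort"])

    labels = timed("label", lambda: label_cohort(table))
    files["labels"] = out / "labels.csv"
    labels.to_frame().to_csv(files["labels"])

    weights = timed("weights", lambda: scoring.make_weights(schema, config.scheme))
    files["weights"] = out / "weights.csv"
    with open(files["weights"], "w") as fh:
        fh.write("variable,weight,scheme\n")
        for name, w in zip(weights.names, weights.weights):
            fh.write(f"{name},{w:.12g},{weights.scheme}\n")

    scores = timed("score", lambda: scoring.score_frame(table, weights, config.threshold))
    files["scores"] = out / "scores.csv"
    scores.to_csv(files["scores"], float_format="%.10g")
    counts["positives"] = int(scores["label"].sum())

    def bench():
        return classify.run_bench(labels, scores["label"].to_numpy(),
                                  protocols=config.protocols, seed=seed_bench)
    report = timed("classification_bench", bench)
    files["classification"] = out / "classification.csv"
    # wall times stay out of checksummed artifacts (they live in the manifest)
    report.to_frame().drop(columns=["seconds"]).to_csv(
        files["classification"], index=False, float_format="%.6g")

    if config.sweep:
        def sweep():
            X = regress.continuous_features(table)
            y = scores["normalized"].to_numpy()
            cfg = replace(config.training, seed=seed_sweep)
            return regress.architecture_sweep(X, y, cfg, config.architectures)
        sweep_frame = timed("regression_sweep", sweep)
        files["sweep"] = out / "sweep.csv"
        sweep_frame.drop(columns=["seconds"]).to_csv(
            files["sweep"], index=False, float_format="%.6g")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {"generate": seed_gen, "bench": seed_bench, "sweep": seed_sweep},
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in files.items()},
        "counts": counts,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
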