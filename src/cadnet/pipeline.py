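"""End-to-end orchestration: generate -> develop -> verify -> demographics.

The study's two-phase protocol is mirrored exactly: model development
(Gensini scoring, noise-subset construction, GA hyperparameter evolution,
final refit and threshold selection) sees only the training and validation
splits; the verification split is read by exactly one operation, the final
blinded report.  Every stage is a pure function of the run configuration
and a single master seed, from which per-stage seeds are derived, and each
stage writes a manifest with file hashes so reruns can be checked for
bit-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortConfig, features_matrix, read_cohort, simulate_cohort, write_cohort
from .elastic_net import ElasticNetParams, predict
from .evaluation import (
    PerformanceReport,
    TrainedModel,
    compare_demographics,
    performance_report,
    select_threshold,
)
from .ga import GAConfig, GeneRanges, SplitData, build_noise_subsets, evolve, fit_genome
from .gensini import GensiniConfig

__all__ = [
    "RunConfig",
    "cmd_generate",
    "cmd_develop",
    "cmd_verify",
    "cmd_demographics",
    "derive_seeds",
]

log = logging.getLogger("cadnet")

COHORT_FILE = "cohort.csv"
LESIONS_FILE = "lesions.csv"
FEATURES_FILE = "features.csv"
MANIFEST_FILE = "manifest.json"
MODEL_FILE = "model.json"
GA_LOG_FILE = "ga_log.csv"
REPORT_FILE = "report.json"

#: Training-noise percentiles that define the four fitness thresholds.
NOISE_PERCENTILES = (60.0, 70.0, 80.0, 90.0)


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(3)
    names = ("cohort", "ga", "bootstrap")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass
class RunConfig:
    """All knobs for a full pipeline run, derived from one master seed.

    The GA budget defaults to a desk-scale run (population 30, at most 30
    generations); the study-scale population of 50 with an open-ended
    budget is available by overriding ``ga``.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gensini: GensiniConfig = field(default_factory=GensiniConfig)
    ga: GAConfig = field(default_factory=lambda: GAConfig(population_size=30, max_generations=30))
    en_tol: float = 1e-5
    en_max_sweeps: int = 1000
    sens_floor: float = 0.90
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        seeds = derive_seeds(self.seed)
        self.cohort = dataclasses.replace(self.cohort, seed=seeds["cohort"])
        self.ga = dataclasses.replace(self.ga, seed=seeds["ga"])
        self.bootstrap_seed = seeds["bootstrap"]

    def en_params(self) -> ElasticNetParams:
        return ElasticNetParams(tol=self.en_tol, max_sweeps=self.en_max_sweeps)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw["cohort"])
        if "ga" in raw:
            kwargs["ga"] = GAConfig(**raw["ga"])
        for key in ("en_tol", "en_max_sweeps", "sens_floor", "n_boot", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "ga": dataclasses.asdict(self.ga),
            "en_tol": self.en_tol,
            "en_max_sweeps": self.en_max_sweeps,
            "sens_floor": self.sens_floor,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def cmd_generate(config: RunConfig, out_dir) -> dict:
    """Simulate the cohort and write the three CSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = simulate_cohort(config.cohort, config.gensini)
    paths = {name: out / name for name in (COHORT_FILE, LESIONS_FILE, FEATURES_FILE)}
    write_cohort(subjects, paths[COHORT_FILE], paths[LESIONS_FILE], paths[FEATURES_FILE])
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "files": {name: _sha256(p) for name, p in paths.items()},
    }
    with open(out / MANIFEST_FILE, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    n_pos = sum(s.cad for s in subjects)
    log.info(
        "generated %d subjects (%d CAD-positive, %.1f%%) into %s",
        len(subjects), n_pos, 100.0 * n_pos / len(subjects), out,
    )
    return manifest


def _split_data(subjects, split: str, n_features: int) -> SplitData:
    rows = [s for s in subjects if s.split == split]
    if not rows:
        raise ValueError(f"cohort contains no {split!r} rows")
    return SplitData(
        X=features_matrix(rows),
        y_gensini=np.array([s.gensini_modified for s in rows]),
        labels=np.array([s.cad for s in rows]),
        noise_volume=np.array([s.noise_volume for s in rows]),
    )


def _load(out_dir) -> tuple[list, dict]:
    out = Path(out_dir)
    subjects = read_cohort(out / COHORT_FILE, out / LESIONS_FILE, out / FEATURES_FILE)
    with open(out / MANIFEST_FILE) as fh:
        manifest = json.load(fh)
    return subjects, manifest


def cmd_develop(config: RunConfig, out_dir) -> TrainedModel:
    """The development phase: GA evolution on train/validation only, a final
    refit of the winning genome, and threshold selection on validation.

    The verification split is filtered out before any computation; the model
    metadata records the audit.
    """
    out = Path(out_dir)
    subjects, manifest = _load(out)
    dev = [s for s in subjects if s.split in ("train", "validation")]
    assert not any(s.split == "verification" for s in dev)
    nf = config.cohort.n_features
    train = _split_data(dev, "train", nf)
    val = _split_data(dev, "validation", nf)
    log.info("development cohort: %d train / %d validation", train.X.shape[0], val.X.shape[0])

    thresholds = np.percentile(train.noise_volume, NOISE_PERCENTILES)
    partition = build_noise_subsets(train.noise_volume, val.noise_volume, thresholds)

    g = np.concatenate([train.y_gensini, val.y_gensini])
    ranges = GeneRanges(gensini_weight_threshold=(float(g.min()), float(g.max())))
    result = evolve(
        train, val, partition, config.ga,
        ranges=ranges, n_reducible=nf, en_params=config.en_params(),
    )
    log.info(
        "GA finished after %d generations (best fitness %.4f%s)",
        result.n_generations, result.best_fitness,
        ", truncated" if result.truncated else "",
    )
    result.history.to_csv(out / GA_LOG_FILE, index=False)

    reduction, weights = fit_genome(
        result.best_genome, train, n_reducible=nf, en_params=config.en_params()
    )
    val_scores = predict(weights, val.X[:, weights.feature_index])
    threshold, info = select_threshold(val_scores, val.labels, config.sens_floor)
    log.info(
        "threshold %.4f on validation: sensitivity %.3f, specificity %.3f%s",
        threshold, info["sensitivity"], info["specificity"],
        " (sensitivity floor unreachable)" if info["warning"] else "",
    )

    model = TrainedModel(
        reduction=reduction,
        weights=weights,
        genome=result.best_genome,
        threshold=threshold,
        feature_hash=manifest["files"][FEATURES_FILE],
        metadata={
            "seed": config.seed,
            "ga_seed": config.ga.seed,
            "n_generations": result.n_generations,
            "best_fitness": result.best_fitness,
            "truncated": result.truncated,
            "noise_thresholds": [float(t) for t in thresholds],
            "sens_floor": config.sens_floor,
            "validation_sensitivity": info["sensitivity"],
            "validation_specificity": info["specificity"],
            "threshold_warning": info["warning"],
            "verification_rows_read": False,
        },
    )
    model.save(out / MODEL_FILE)
    return model


def cmd_verify(config: RunConfig, out_dir, model_path=None) -> PerformanceReport:
    """The blinded verification phase: apply the frozen model once to the
    verification split and report metrics with BCa bootstrap intervals."""
    out = Path(out_dir)
    subjects, manifest = _load(out)
    model = TrainedModel.load(model_path or out / MODEL_FILE)
    if model.feature_hash != manifest["files"][FEATURES_FILE]:
        raise ValueError(
            "feature-matrix hash mismatch: this model was developed on a "
            "different cohort than the one being verified"
        )
    verif = _split_data(subjects, "verification", config.cohort.n_features)
    scores = model.scores(verif.X)
    report = performance_report(
        scores, verif.labels, model.threshold,
        n_boot=config.n_boot, seed=config.bootstrap_seed,
    )
    with open(out / REPORT_FILE, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    (out / "report.txt").write_text(report.to_text() + "\n")
    log.info("verification report:\n%s", report.to_text())
    return report


def cmd_demographics(out_dir):
    """Table-1-style development vs verification comparison."""
    out = Path(out_dir)
    subjects, _ = _load(out)
    dev = [s for s in subjects if s.split in ("train", "validation")]
    verif = [s for s in subjects if s.split == "verification"]

    def group(rows):
        return {
            "age": np.array([s.age for s in rows]),
            "male": np.array([s.sex == "male" for s in rows]),
            "bmi": np.array([s.bmi for s in rows]),
            "heart_rate": np.array([s.heart_rate for s in rows]),
            "cad_positive": np.array([s.cad for s in rows]),
        }

    table = compare_demographics(group(dev), group(verif))
    table.insert(1, "n_a", len(dev))
    table.insert(2, "n_b", len(verif))
    table.to_csv(out / "demographics.csv", index=False)
    return table
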