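"""One-command orchestration: simulate -> screen -> infer -> network.

A run is described by a :class:`PipelineConfig` (usually loaded from a
YAML file), executed into a run directory containing every stage's
artifact plus a JSON manifest (config echo, derived stage seeds, package
version, per-stage wall times).  Re-running the same config and master
seed reproduces every artifact byte-for-byte; only manifest timings
differ.

Stage seeds are derived from the master seed by stable hashing of the
stage name, so adding a stage never perturbs earlier stages' randomness,
and any stage can be re-run standalone from the previous stage's files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data import (read_expression_matrix, read_labels, derive_labels,
                   write_expression_matrix, write_labels)
from .mlp import Hyperparameters
from .network import export_network, filter_top_edges, hub_scores, recovery_report
from .screen import ProbeScreen, DEFAULT_TOP_K, DEFAULT_RESAMPLES
from .interactions import InteractionModel
from .synthetic import (SyntheticTruth, generate_truth, simulate_expression,
                        DEFAULT_BETA_RANGE, DEFAULT_DRIVER_EFFECT,
                        DEFAULT_NOISE_SD)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class SyntheticBlock:
    n_probes: int = 50
    n_associated: int = 10
    n_edges: int = 6
    n_samples: int = 200
    beta_range: tuple[float, float] = DEFAULT_BETA_RANGE
    driver_effect: float = DEFAULT_DRIVER_EFFECT
    noise_sd: float = DEFAULT_NOISE_SD
    prevalence: float = 0.5


@dataclass
class ScreeningBlock:
    resamples: int = DEFAULT_RESAMPLES
    top_k: int = DEFAULT_TOP_K


@dataclass
class InferenceBlock:
    resamples: int = DEFAULT_RESAMPLES
    method: str = "weights"
    top_edges: int = 100


@dataclass
class PipelineConfig:
    """Full description of one pipeline run.

    Exactly one of ``expression`` (a TSV path) or ``synthetic`` (a
    generation block) must be given.  With a real matrix, the phenotype
    comes from ``labels`` (a TSV path) or is derived by a median split on
    ``driver_probe``.
    """

    seed: int = 0
    expression: str | None = None
    labels: str | None = None
    driver_probe: str | None = None
    synthetic: SyntheticBlock | None = None
    screening: ScreeningBlock = field(default_factory=ScreeningBlock)
    inference: InferenceBlock = field(default_factory=InferenceBlock)
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self) -> None:
        if (self.expression is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of 'expression' and 'synthetic' must be configured")
        if self.expression is not None:
            if (self.labels is None) == (self.driver_probe is None):
                raise ConfigError(
                    "with an expression path, give exactly one of "
                    "'labels' and 'driver_probe'")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        for key, blk in (("synthetic", SyntheticBlock),
                         ("screening", ScreeningBlock),
                         ("inference", InferenceBlock),
                         ("hyperparameters", Hyperparameters)):
            if isinstance(doc.get(key), dict):
                sub = dict(doc[key])
                if key == "synthetic" and "beta_range" in sub:
                    sub["beta_range"] = tuple(sub["beta_range"])
                try:
                    doc[key] = blk(**sub)
                except TypeError as exc:
                    raise ConfigError(f"invalid '{key}' block: {exc}") from None
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        doc = asdict(self)
        return doc

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage seed from the master seed and a stable hash of the stage name."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir`` and return its path.

    Artifacts: ``expression.tsv``, ``labels.tsv`` (+ ``truth.json`` for
    synthetic runs), ``screen.tsv``, ``markers.txt``,
    ``interactions.tsv``/``interactions.long.tsv``,
    ``network.sif``/``network.edges.tsv``/``network.nodes.tsv``
    (+ ``recovery.json``), and ``manifest.json``.  A stage failure aborts
    with the stage name; earlier artifacts are retained for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(out / "run.log")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("anninfer")
    root.addHandler(log_file)
    tag = f"config={config.config_hash}"
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "master_seed": config.seed,
        "stage_seeds": {},
        "wall_times_s": {},
    }
    timings = manifest["wall_times_s"]

    def _stage(name: str):
        seed = stage_seed(config.seed, name)
        manifest["stage_seeds"][name] = seed
        logger.info("stage %s (seed %d)", name, seed)
        return seed, time.perf_counter()

    try:
        # ---- data -------------------------------------------------------
        seed, t0 = _stage("data")
        truth: SyntheticTruth | None = None
        if config.synthetic is not None:
            syn = config.synthetic
            truth = generate_truth(syn.n_probes, syn.n_associated, syn.n_edges,
                                   syn.beta_range, seed,
                                   syn.driver_effect, syn.noise_sd)
            matrix, labels = simulate_expression(truth, syn.n_samples,
                                                 seed, syn.prevalence)
            truth.to_json(out / "truth.json")
        else:
            matrix = read_expression_matrix(config.expression)
            if config.labels is not None:
                labels = read_labels(config.labels)
            else:
                labels = derive_labels(matrix, config.driver_probe)
        write_expression_matrix(matrix, out / "expression.tsv",
                                seed=config.seed, provenance=tag)
        write_labels(labels, out / "labels.tsv", seed=config.seed, provenance=tag)
        timings["data"] = round(time.perf_counter() - t0, 3)

        # ---- screen -----------------------------------------------------
        seed, t0 = _stage("screen")
        screen = ProbeScreen(matrix, labels).fit(
            config.screening.resamples, config.hyperparameters, seed)
        screen.to_tsv(out / "screen.tsv", provenance=tag)
        markers = screen.select_top(config.screening.top_k)
        (out / "markers.txt").write_text(
            "\n".join(markers) + "\n", encoding="utf-8")
        timings["screen"] = round(time.perf_counter() - t0, 3)

        # ---- infer ------------------------------------------------------
        seed, t0 = _stage("infer")
        interactions = InteractionModel(matrix.subset(markers)).fit(
            config.inference.resamples, config.hyperparameters, seed,
            config.inference.method)
        interactions.to_tsv(out / "interactions.tsv", provenance=tag)
        interactions.to_long_tsv(out / "interactions.long.tsv", provenance=tag)
        timings["infer"] = round(time.perf_counter() - t0, 3)

        # ---- network ----------------------------------------------------
        seed, t0 = _stage("network")
        edges = filter_top_edges(interactions, config.inference.top_edges)
        hubs = hub_scores(edges, interactions.marker_ids)
        export_network(edges, hubs, out / "network",
                       seed=config.seed, provenance=tag)
        if truth is not None:
            index = {truth.probe_id(g): g for g in range(truth.n_probes)}
            report = recovery_report(edges, truth,
                                     {m: index[m] for m in interactions.marker_ids})
            (out / "recovery.json").write_text(
                json.dumps(report.as_dict(), indent=1), encoding="utf-8")
        timings["network"] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        done = set(timings)
        stage = next((s for s in ("data", "screen", "infer", "network")
                      if s not in done), "network")
        logger.error("stage %s failed: %s", stage, exc)
        root.removeHandler(log_file)
        log_file.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                       encoding="utf-8")
    root.removeHandler(log_file)
    log_file.close()
    return out
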