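"""Synthetic expression data with a latent binary driver and planted edges.

The generator emulates the statistical structure the pipeline assumes in a
real cohort: a latent two-class driver phenotype (e.g. low/high expression
of an oncogenic driver) that shifts a subset of probes, plus directed,
signed regulatory dependencies between probes, all under Gaussian noise.

The model is linear-Gaussian.  For sample ``s`` with drawn class
``c_s in {0, 1}``:

    x[g, s] = driver_effects[g] * c_s + eps[g, s],   eps ~ N(0, noise_sd^2)

followed by a single in-index-order propagation sweep in which each
planted edge ``(src, tgt, beta)`` adds ``beta * x[src, s]`` to
``x[tgt, s]``.  One sweep in target order creates detectable directed
dependence and is cycle-safe (a cycle simply truncates after one pass);
no structural-equation fixed point is solved.

Defaults (driver effect 2.0, |beta| in [1, 2], noise SD 0.5, class
prevalence 0.5) give effect sizes at which screening and inference succeed
with a few hundred samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import ExpressionMatrix, PhenotypeLabels

__all__ = ["SyntheticTruth", "generate_truth", "simulate_expression"]

DEFAULT_DRIVER_EFFECT = 2.0
DEFAULT_BETA_RANGE = (1.0, 2.0)
DEFAULT_NOISE_SD = 0.5


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic cohort: driver structure and planted edges.

    ``driver_effects[g]`` is the additive shift of probe ``g`` in class-1
    samples (0 for unassociated probes).  ``planted_edges`` holds
    ``(source_index, target_index, beta)`` triples with signed regulatory
    coefficients.
    """

    n_probes: int
    driver_probe_index: int
    driver_effects: np.ndarray
    planted_edges: tuple[tuple[int, int, float], ...]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "driver_effects",
                           np.asarray(self.driver_effects, dtype=float))
        object.__setattr__(self, "planted_edges",
                           tuple((int(s), int(t), float(b))
                                 for s, t, b in self.planted_edges))
        if self.driver_effects.shape != (self.n_probes,):
            raise ValueError("driver_effects must have one entry per probe")
        if not 0 <= self.driver_probe_index < self.n_probes:
            raise ValueError("driver_probe_index out of range")
        if self.driver_effects[self.driver_probe_index] == 0:
            raise ValueError("the driver probe must have a nonzero driver effect")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        seen = set()
        for s, t, _ in self.planted_edges:
            if s == t:
                raise ValueError(f"self-loop planted at probe {s}")
            if not (0 <= s < self.n_probes and 0 <= t < self.n_probes):
                raise ValueError(f"edge ({s}, {t}) out of range")
            if (s, t) in seen:
                raise ValueError(f"duplicate planted edge ({s}, {t})")
            seen.add((s, t))

    @property
    def edge_set(self) -> dict[tuple[int, int], float]:
        """Mapping (source, target) -> beta."""
        return {(s, t): b for s, t, b in self.planted_edges}

    @property
    def associated_indices(self) -> np.ndarray:
        """Probes with a nonzero driver effect."""
        return np.nonzero(self.driver_effects != 0)[0]

    def probe_id(self, index: int) -> str:
        return f"P{index + 1:04d}"

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_probes": self.n_probes,
            "driver_probe_index": self.driver_probe_index,
            "driver_effects": self.driver_effects.tolist(),
            "planted_edges": [list(e) for e in self.planted_edges],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        return cls(doc["n_probes"], doc["driver_probe_index"],
                   np.array(doc["driver_effects"]),
                   tuple(tuple(e) for e in doc["planted_edges"]),
                   doc["noise_sd"], doc["seed"])


def generate_truth(n_probes: int, n_associated: int, n_edges: int,
                   beta_range: tuple[float, float] = DEFAULT_BETA_RANGE,
                   seed: int = 0,
                   driver_effect: float = DEFAULT_DRIVER_EFFECT,
                   noise_sd: float = DEFAULT_NOISE_SD) -> SyntheticTruth:
    """Draw a ground-truth structure.

    ``n_associated`` probes (a random subset including the driver) receive
    driver effect ``driver_effect``; ``n_edges`` directed edges are sampled
    without replacement among ordered pairs of associated probes — planting
    edges only among driver-associated probes ensures they survive the
    screening stage — with |beta| uniform in ``beta_range`` and random sign.
    """
    if not 1 <= n_associated <= n_probes:
        raise ValueError("need 1 <= n_associated <= n_probes")
    max_edges = n_associated * (n_associated - 1)
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}] "
                         f"for {n_associated} associated probes")
    lo, hi = beta_range
    if not 0 < lo <= hi:
        raise ValueError("beta_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    associated = np.sort(rng.choice(n_probes, size=n_associated, replace=False))
    driver = int(associated[0])
    effects = np.zeros(n_probes)
    effects[associated] = driver_effect
    # ordered pairs of associated probes, excluding the diagonal
    pair_codes = rng.choice(max_edges, size=n_edges, replace=False)
    edges = []
    for code in pair_codes:
        i, j = divmod(int(code), n_associated - 1)
        if j >= i:
            j += 1
        beta = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
        edges.append((int(associated[i]), int(associated[j]), beta))
    return SyntheticTruth(n_probes, driver, effects, tuple(edges),
                          noise_sd, int(seed))


def simulate_expression(truth: SyntheticTruth, n_samples: int, seed: int = 0,
                        prevalence: float = 0.5
                        ) -> tuple[ExpressionMatrix, PhenotypeLabels]:
    """Simulate a cohort from a ground-truth structure.

    Classes are drawn Bernoulli(``prevalence``); if a draw leaves one
    class empty (possible at small ``n_samples``) the class vector is
    redrawn.  Probe IDs are ``P0001..``, sample IDs ``S0001..``.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = (rng.random(n_samples) < prevalence).astype(int)
    while classes.min() == classes.max():
        classes = (rng.random(n_samples) < prevalence).astype(int)
    x = truth.driver_effects[:, None] * classes[None, :]
    x = x + rng.normal(0.0, truth.noise_sd, size=(truth.n_probes, n_samples))
    # one propagation sweep in target-index order (cycle-safe)
    by_target = sorted(truth.planted_edges, key=lambda e: (e[1], e[0]))
    for s, t, beta in by_target:
        x[t] += beta * x[s]
    probe_ids = [truth.probe_id(g) for g in range(truth.n_probes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(probe_ids, sample_ids, x)
    labels = PhenotypeLabels(sample_ids, classes)
    return matrix, labels
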