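"""Monte Carlo cross-validated single-probe screening.

Every probe is scored by how well a one-input perceptron predicts the
binary driver phenotype from that probe alone.  For each of
``n_resamples`` Monte Carlo resamples, the samples are randomly
partitioned 60/20/20 into training (weight updates), test (early-stopping
monitor) and validation (completely blind) subsets; the probe's score is
the mean validation-subset MSE over resamples, so lower scores mean
stronger association with the phenotype.  Ranking on the blind validation
subset, rather than the early-stopping test subset, avoids the optimism
of the set that steered training.

``ProbeScreen`` is the model object; ``fit`` returns a ``ScreenResults``
carrying scores, resample SDs, ranks and the top-k selection.  The
functional surface (:func:`make_splits`, :func:`score_probe`,
:func:`rank_probes`, :func:`select_top`) wraps the same computation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, PhenotypeLabels, _provenance_header
from .mlp import Hyperparameters, train
from ._kernels import predict_batch

__all__ = [
    "SplitIndices",
    "ScreenResults",
    "ProbeScreen",
    "make_splits",
    "score_probe",
    "rank_probes",
    "select_top",
]

DEFAULT_TOP_K = 100
DEFAULT_RESAMPLES = 10
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SplitIndices:
    """A 60/20/20 train/test/validation partition of sample indices."""

    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        for name in ("train", "test", "validation"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.int64))

    @property
    def n_samples(self) -> int:
        return self.train.size + self.test.size + self.validation.size


def make_splits(n_samples: int,
                seed: int | np.random.SeedSequence | np.random.Generator = 0
                ) -> SplitIndices:
    """Randomly partition ``n_samples`` indices 60/20/20.

    Test and validation each receive ``floor(0.2 * n)`` samples; training
    receives the remainder (>= 60%).  Requires ``n_samples >= 5`` so that
    every subset is non-empty.
    """
    if n_samples < 5:
        raise ValueError("n_samples must be >= 5 (each subset must be non-empty)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_hold = n_samples // 5
    n_train = n_samples - 2 * n_hold
    return SplitIndices(train=perm[:n_train],
                        test=perm[n_train:n_train + n_hold],
                        validation=perm[n_train + n_hold:])


def _scale01(row: np.ndarray) -> np.ndarray:
    lo, hi = row.min(), row.max()
    if hi == lo:
        raise ValueError("constant probe row cannot be scaled")
    return (row - lo) / (hi - lo)


def _probe_seed(master_seed: int, probe_id: str) -> int:
    """Per-probe seed from the master seed and a stable hash of the probe ID.

    Depending on the ID rather than the row position makes scores
    invariant under row reordering.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(probe_id.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _score_scaled_probe(x: np.ndarray, y: np.ndarray, n_resamples: int,
                        hyper: Hyperparameters, seed: int) -> tuple[float, float]:
    """Mean and SD of validation MSE over resamples for one scaled probe."""
    n = x.shape[0]
    X = x[:, None]
    vals = np.empty(n_resamples)
    for r in range(1, n_resamples + 1):
        resample_seed = int(seed) ^ r
        for attempt in range(_MAX_REDRAWS):
            ss = np.random.SeedSequence([resample_seed, attempt])
            s_split, s_train = ss.spawn(2)
            splits = make_splits(n, s_split)
            if y[splits.train].min() != y[splits.train].max():
                break
        else:
            raise ValueError("could not draw a training split containing "
                             "both classes after 100 attempts")
        model, _ = train(X, y, splits.train, splits.test, hyper, s_train)
        pred = predict_batch(model.W1, model.W2, X[splits.validation])
        vals[r - 1] = float(np.mean((pred - y[splits.validation]) ** 2))
    return float(vals.mean()), float(vals.std(ddof=0))


def score_probe(matrix: ExpressionMatrix, labels: PhenotypeLabels, probe: str,
                n_resamples: int = DEFAULT_RESAMPLES,
                hyper: Hyperparameters | None = None, seed: int = 0) -> float:
    """Mean Monte Carlo validation MSE of a one-probe phenotype model."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    hyper = hyper or Hyperparameters()
    x = _scale01(matrix.row(probe))
    y = labels.aligned_to(matrix.sample_ids).astype(float)
    mean, _ = _score_scaled_probe(x, y, n_resamples, hyper, seed)
    return mean


class ScreenResults:
    """Results of a probe screen: scores, ranks and the selection rule.

    Attributes
    ----------
    probe_ids : list of str
        Probes in the input matrix's row order.
    scores : ndarray
        Mean validation MSE per probe (lower = more phenotype-associated).
    score_sd : ndarray
        SD of the per-resample validation MSEs (a stability diagnostic).
    ranks : ndarray
        1-based ranks by ascending score; ties broken by probe ID.
    """

    def __init__(self, probe_ids: list[str], scores: np.ndarray,
                 score_sd: np.ndarray, n_resamples: int, seed: int):
        self.probe_ids = list(probe_ids)
        self.scores = np.asarray(scores, dtype=float)
        self.score_sd = np.asarray(score_sd, dtype=float)
        self.n_resamples = int(n_resamples)
        self.seed = int(seed)
        if self.scores.shape != (len(self.probe_ids),):
            raise ValueError("one score per probe required")
        if not np.all(np.isfinite(self.scores)) or self.scores.min() < 0:
            raise ValueError("scores must be finite and >= 0")
        order = sorted(range(len(self.probe_ids)),
                       key=lambda i: (self.scores[i], self.probe_ids[i]))
        ranks = np.empty(len(order), dtype=np.int64)
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        self.ranks = ranks

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probe_ids,
            "score": self.scores,
            "score_sd": self.score_sd,
            "rank": self.ranks,
        })

    def rank_of(self, probe_id: str) -> int:
        return int(self.ranks[self.probe_ids.index(probe_id)])

    def select_top(self, k: int = DEFAULT_TOP_K) -> list[str]:
        """The ``min(k, n_probes)`` best-ranked probe IDs, in rank order."""
        if k < 1:
            raise ValueError("k must be >= 1")
        ordered = sorted(self.probe_ids, key=self.rank_of)
        return ordered[:min(k, len(ordered))]

    def summary(self, top: int = 10) -> str:
        df = self.frame.sort_values("rank").head(top)
        lines = [
            "Probe screen (Monte Carlo cross-validated 1-probe MLPs)",
            f"  probes: {len(self.probe_ids)}   resamples: {self.n_resamples}"
            f"   seed: {self.seed}",
            f"  score: mean validation MSE (lower = stronger association)",
            "",
            df.to_string(index=False,
                         formatters={"score": "{:.4f}".format,
                                     "score_sd": "{:.4f}".format}),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path, provenance: str | None = None) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_header(self.seed, provenance))
            fh.write(f"# n_resamples={self.n_resamples}\n")
            fh.write("probe_id\tscore\tscore_sd\trank\n")
            for pid, s, sd, r in zip(self.probe_ids, self.scores,
                                     self.score_sd, self.ranks):
                fh.write(f"{pid}\t{float(s)!r}\t{float(sd)!r}\t{r}\n")
        return path


class ProbeScreen:
    """Screen every probe of an expression matrix against a binary phenotype.

    Parameters
    ----------
    matrix : ExpressionMatrix
    labels : PhenotypeLabels
        Must cover exactly the matrix's samples (any order).
    """

    def __init__(self, matrix: ExpressionMatrix, labels: PhenotypeLabels):
        self.matrix = matrix
        self.labels = labels
        self._y = labels.aligned_to(matrix.sample_ids).astype(float)

    def fit(self, n_resamples: int = DEFAULT_RESAMPLES,
            hyper: Hyperparameters | None = None, seed: int = 0) -> ScreenResults:
        """Score and rank every probe; deterministic given ``seed``."""
        if n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        hyper = hyper or Hyperparameters()
        scores = np.empty(self.matrix.n_probes)
        sds = np.empty(self.matrix.n_probes)
        for i, pid in enumerate(self.matrix.probe_ids):
            x = _scale01(self.matrix.values[i])
            scores[i], sds[i] = _score_scaled_probe(
                x, self._y, n_resamples, hyper, _probe_seed(seed, pid))
        return ScreenResults(self.matrix.probe_ids, scores, sds,
                             n_resamples, seed)


def rank_probes(matrix: ExpressionMatrix, labels: PhenotypeLabels,
                n_resamples: int = DEFAULT_RESAMPLES,
                hyper: Hyperparameters | None = None,
                seed: int = 0) -> ScreenResults:
    """Functional wrapper around ``ProbeScreen(matrix, labels).fit(...)``."""
    return ProbeScreen(matrix, labels).fit(n_resamples, hyper, seed)


def select_top(result: ScreenResults, k: int = DEFAULT_TOP_K) -> list[str]:
    """The top-k probes of a screen, in rank order (clamped to n_probes)."""
    return result.select_top(k)
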