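"""Interaction inference from trained network weights (the ANNi stage).

For each marker ``t`` in a selected panel, a perceptron is trained to
predict the min-max-scaled expression of ``t`` from all other markers,
over Monte Carlo resamples; the trained weights are then collapsed into a
signed influence score per input.  The default score is the
connection-weight product

    influence(i) = sum_h W1[i, h] * W2[h]        (bias weights excluded),

whose sign carries the putative regulation direction (positive =
activation, negative = repression) and whose magnitude carries strength.
A sensitivity alternative — move input ``i`` from 0 to 1 with the other
inputs held at their training means and record the output change — is
available as ``method="sensitivity"``.

Influences averaged over resamples fill column ``t`` of the directed
marker x marker interaction matrix; the diagonal is structurally zero
because a marker is never an input to its own model.  Both directions
(i -> j and j -> i) are estimated independently; nothing is symmetrised.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, _provenance_header, minmax_scale
from .mlp import Hyperparameters, MLPModel, TrainingDivergedError, train
from .screen import make_splits, DEFAULT_RESAMPLES

__all__ = [
    "InteractionModel",
    "InteractionResults",
    "InferenceError",
    "influence_scores",
    "sensitivity_scores",
    "infer_interactions",
]

logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    """All resamples failed for some target marker."""


def influence_scores(model: MLPModel) -> np.ndarray:
    """Connection-weight influence of each input: sum_h W1[i,h] * W2[h]."""
    return model.W1[:-1, :] @ model.W2[:-1]


def sensitivity_scores(model: MLPModel, reference: np.ndarray) -> np.ndarray:
    """Output change when each input moves 0 -> 1, others at `reference`."""
    from .mlp import forward
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.shape[0] != model.n_inputs:
        raise ValueError("reference length must equal n_inputs")
    out = np.empty(model.n_inputs)
    for i in range(model.n_inputs):
        x = reference.copy()
        x[i] = 0.0
        _, lo = forward(model, x)
        x[i] = 1.0
        _, hi = forward(model, x)
        out[i] = hi - lo
    return out


class InteractionResults:
    """A directed, signed marker x marker influence matrix.

    ``values[i, j]`` is the mean influence of source marker ``i`` on
    target marker ``j`` over resamples; ``resample_sd`` holds the
    corresponding per-entry SDs (diagnostic only).
    """

    def __init__(self, marker_ids: list[str], values: np.ndarray,
                 resample_sd: np.ndarray, n_resamples: int, seed: int,
                 method: str = "weights", n_skipped: int = 0):
        self.marker_ids = list(marker_ids)
        self.values = np.asarray(values, dtype=float)
        self.resample_sd = np.asarray(resample_sd, dtype=float)
        self.n_resamples = int(n_resamples)
        self.seed = int(seed)
        self.method = method
        self.n_skipped = int(n_skipped)
        m = len(self.marker_ids)
        if self.values.shape != (m, m):
            raise ValueError("values must be m x m")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("influences must be finite")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.marker_ids,
                            columns=self.marker_ids)

    def top_edges(self, k: int = 100):
        from .network import filter_top_edges
        return filter_top_edges(self, k)

    def summary(self, top: int = 10) -> str:
        from .network import filter_top_edges
        edges = filter_top_edges(self, top)
        rows = [(e.source, e.target, e.influence, e.sign) for e in edges.edges]
        df = pd.DataFrame(rows, columns=["source", "target", "influence", "sign"])
        lines = [
            "Interaction inference (per-marker MLPs, "
            f"{self.method} influence scores)",
            f"  markers: {len(self.marker_ids)}   resamples: {self.n_resamples}"
            f"   seed: {self.seed}   skipped resamples: {self.n_skipped}",
            "",
            f"Strongest {len(rows)} directed interactions:",
            df.to_string(index=False,
                         formatters={"influence": "{:+.4f}".format}),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path, provenance: str | None = None) -> Path:
        """Square TSV with marker IDs on both axes."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_header(self.seed, provenance))
            fh.write(f"# n_resamples={self.n_resamples} method={self.method}\n")
            fh.write("marker_id\t" + "\t".join(self.marker_ids) + "\n")
            for mid, row in zip(self.marker_ids, self.values):
                fh.write(mid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        return path

    def to_long_tsv(self, path: str | Path, provenance: str | None = None) -> Path:
        """Long-format TSV: source, target, influence (off-diagonal only)."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_provenance_header(self.seed, provenance))
            fh.write("source\ttarget\tinfluence\n")
            for i, src in enumerate(self.marker_ids):
                for j, tgt in enumerate(self.marker_ids):
                    if i != j:
                        fh.write(f"{src}\t{tgt}\t{float(self.values[i, j])!r}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionResults":
        meta = {"seed": 0, "n_resamples": 0, "method": "weights"}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k in ("seed", "n_resamples"):
                            meta[k] = int(v)
                        elif k == "method":
                            meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0,
                         float_precision="round_trip")
        values = df.to_numpy(dtype=float)
        return cls(list(map(str, df.index)), values, np.zeros_like(values),
                   meta["n_resamples"], meta["seed"], meta["method"])


class InteractionModel:
    """Infer pairwise influences among the markers of an expression matrix.

    The matrix rows (markers) are min-max scaled on construction so that
    every marker can serve as a (0, 1)-bounded network target.  Requires
    at least two markers.
    """

    def __init__(self, matrix: ExpressionMatrix):
        if matrix.n_probes < 2:
            raise ValueError("need at least 2 markers")
        scaled, self._params = minmax_scale(matrix)
        self.matrix = scaled
        self.marker_ids = list(scaled.probe_ids)

    def fit(self, n_resamples: int = DEFAULT_RESAMPLES,
            hyper: Hyperparameters | None = None, seed: int = 0,
            method: str = "weights") -> InteractionResults:
        """Train per-target MLPs over resamples and average influences.

        Per-(target, resample) seeds are derived deterministically from
        ``seed``, the target index and the resample index, so any single
        target can be recomputed in isolation.  A resample whose training
        diverges is skipped with a warning; if every resample for a target
        fails, an :class:`InferenceError` names the target.
        """
        if n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if method not in ("weights", "sensitivity"):
            raise ValueError("method must be 'weights' or 'sensitivity'")
        hyper = hyper or Hyperparameters()
        Xall = np.ascontiguousarray(self.matrix.values.T)  # samples x markers
        n, m = Xall.shape
        values = np.zeros((m, m))
        sds = np.zeros((m, m))
        n_skipped = 0
        source_rows = [np.array([i for i in range(m) if i != t]) for t in range(m)]
        for t in range(m):
            X = np.ascontiguousarray(Xall[:, source_rows[t]])
            y = Xall[:, t]
            collected = []
            for r in range(n_resamples):
                ss = np.random.SeedSequence([int(seed), t, r])
                s_split, s_train = ss.spawn(2)
                splits = make_splits(n, s_split)
                try:
                    model, _ = train(X, y, splits.train, splits.test,
                                     hyper, s_train)
                except TrainingDivergedError:
                    logger.warning("target %s resample %d diverged; skipped",
                                   self.marker_ids[t], r)
                    n_skipped += 1
                    continue
                if method == "weights":
                    infl = influence_scores(model)
                else:
                    infl = sensitivity_scores(model, X[splits.train].mean(axis=0))
                collected.append(infl)
            if not collected:
                raise InferenceError(
                    f"all {n_resamples} resamples failed for target "
                    f"{self.marker_ids[t]!r}")
            stack = np.vstack(collected)
            values[source_rows[t], t] = stack.mean(axis=0)
            sds[source_rows[t], t] = stack.std(axis=0, ddof=0)
        return InteractionResults(self.marker_ids, values, sds,
                                  n_resamples, seed, method, n_skipped)


def infer_interactions(matrix: ExpressionMatrix,
                       n_resamples: int = DEFAULT_RESAMPLES,
                       hyper: Hyperparameters | None = None, seed: int = 0,
                       method: str = "weights") -> InteractionResults:
    """Functional wrapper around ``InteractionModel(matrix).fit(...)``."""
    return InteractionModel(matrix).fit(n_resamples, hyper, seed, method)
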