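"""Edge filtering, hub ranking, recovery scoring and Cytoscape export."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data import ValidationError, _provenance_header
from .synthetic import SyntheticTruth

__all__ = [
    "Edge",
    "EdgeList",
    "RecoveryReport",
    "filter_top_edges",
    "hub_scores",
    "recovery_report",
    "export_network",
]


@dataclass(frozen=True)
class Edge:
    """One directed, signed interaction."""

    source: str
    target: str
    influence: float

    @property
    def sign(self) -> str:
        return "positive" if self.influence > 0 else "negative"


@dataclass(frozen=True)
class EdgeList:
    """Edges retained after top-k filtering, strongest first.

    Sorted by |influence| descending, ties broken by (source, target).
    """

    edges: tuple[Edge, ...]
    k_requested: int

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.influence, e.sign) for e in self.edges],
            columns=["source", "target", "influence", "sign"])


def _matrix_parts(interactions) -> tuple[list[str], np.ndarray]:
    """Accept an InteractionResults or a (marker_ids, values) pair."""
    if hasattr(interactions, "marker_ids") and hasattr(interactions, "values"):
        return list(interactions.marker_ids), np.asarray(interactions.values, float)
    ids, values = interactions
    return list(ids), np.asarray(values, float)


def filter_top_edges(interactions, k: int = 100) -> EdgeList:
    """Retain the k strongest directed interactions by |influence|.

    ``k`` clamps to the number of off-diagonal entries.  Ties in
    |influence| are broken by (source, target) lexicographic order so the
    result is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids, values = _matrix_parts(interactions)
    m = len(ids)
    entries = [Edge(ids[i], ids[j], float(values[i, j]))
               for i in range(m) for j in range(m) if i != j]
    entries.sort(key=lambda e: (-abs(e.influence), e.source, e.target))
    return EdgeList(tuple(entries[:min(k, len(entries))]), k_requested=k)


def hub_scores(edges: EdgeList, marker_ids: list[str]) -> pd.DataFrame:
    """Rank markers by connectivity (sum of |influence| of incident edges).

    Returns a DataFrame with columns marker_id, connectivity, degree and
    rank (1 = strongest hub, ties broken by marker ID); includes every
    marker, with zeros for markers touching no retained edge.
    """
    known = set(marker_ids)
    connectivity = {m: 0.0 for m in marker_ids}
    degree = {m: 0 for m in marker_ids}
    for e in edges:
        if e.source not in known or e.target not in known:
            raise ValidationError(
                f"edge endpoint not in marker list: {e.source!r} -> {e.target!r}")
        connectivity[e.source] += abs(e.influence)
        connectivity[e.target] += abs(e.influence)
        degree[e.source] += 1
        degree[e.target] += 1
    df = pd.DataFrame({
        "marker_id": list(marker_ids),
        "connectivity": [connectivity[m] for m in marker_ids],
        "degree": [degree[m] for m in marker_ids],
    })
    order = df.sort_values(["connectivity", "marker_id"],
                           ascending=[False, True]).index
    rank = pd.Series(index=order, data=np.arange(1, len(df) + 1))
    df["rank"] = rank.sort_index().to_numpy()
    return df.sort_values("rank").reset_index(drop=True)


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery of planted edges by a filtered network."""

    precision: float
    recall: float
    sign_accuracy: float
    auroc: float
    n_edges: int
    n_planted: int

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "sign_accuracy": self.sign_accuracy,
            "auroc": self.auroc,
            "n_edges": float(self.n_edges),
            "n_planted": float(self.n_planted),
        }


def recovery_report(edges: EdgeList, truth: SyntheticTruth,
                    marker_index: dict[str, int]) -> RecoveryReport:
    """Score a filtered edge list against planted ground truth.

    ``marker_index`` maps every marker ID appearing in the network to its
    probe index in the truth.  Precision is the fraction of retained
    edges that are planted; recall is the fraction of all planted edges
    recovered; sign accuracy is the fraction of recovered planted edges
    whose influence sign matches the planted beta's sign.  The AUROC
    treats |influence| as a score for edge-vs-non-edge over all ordered
    marker pairs (pairs outside the retained list score 0); planted edges
    with an endpoint outside the marker universe cannot be recovered and
    count against recall but are excluded from the AUROC universe.
    """
    for e in edges:
        if e.source not in marker_index or e.target not in marker_index:
            raise ValidationError(
                f"marker mapping incomplete: {e.source!r} or {e.target!r}")
    planted = truth.edge_set
    retained: dict[tuple[int, int], float] = {}
    for e in edges:
        retained[(marker_index[e.source], marker_index[e.target])] = e.influence
    hits = [pair for pair in retained if pair in planted]
    precision = len(hits) / len(edges) if len(edges) else 0.0
    recall = len(hits) / len(planted) if planted else 0.0
    if hits:
        sign_acc = float(np.mean([np.sign(retained[p]) == np.sign(planted[p])
                                  for p in hits]))
    else:
        sign_acc = 0.0 if planted else 1.0
    # AUROC over all ordered pairs of the marker universe
    markers = sorted(set(marker_index[m] for m in marker_index))
    y_true, y_score = [], []
    for i in markers:
        for j in markers:
            if i == j:
                continue
            y_true.append(1 if (i, j) in planted else 0)
            y_score.append(abs(retained.get((i, j), 0.0)))
    if len(set(y_true)) < 2:
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, y_score))
    return RecoveryReport(precision, recall, sign_acc, auroc,
                          n_edges=len(edges), n_planted=len(planted))


def export_network(edges: EdgeList, hubs: pd.DataFrame,
                   out_prefix: str | Path, seed: int | None = None,
                   provenance: str | None = None) -> dict[str, Path]:
    """Write Cytoscape-loadable files for a filtered network.

    Produces ``<prefix>.sif`` (source, relation, target; relation is
    ``activates`` for positive influence, ``represses`` for negative),
    ``<prefix>.edges.tsv`` (edge attributes) and ``<prefix>.nodes.tsv``
    (node attributes).  Output bytes are a pure function of the inputs.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sif = prefix.with_suffix(prefix.suffix + ".sif")
    with open(sif, "w", encoding="utf-8") as fh:
        for e in edges:
            relation = "activates" if e.sign == "positive" else "represses"
            fh.write(f"{e.source}\t{relation}\t{e.target}\n")
    edge_path = prefix.with_suffix(prefix.suffix + ".edges.tsv")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, provenance))
        fh.write("source\ttarget\tinfluence\tsign\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{e.influence!r}\t{e.sign}\n")
    node_path = prefix.with_suffix(prefix.suffix + ".nodes.tsv")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, provenance))
        fh.write("marker_id\tconnectivity\tdegree\trank\n")
        for row in hubs.itertuples(index=False):
            fh.write(f"{row.marker_id}\t{float(row.connectivity)!r}"
                     f"\t{row.degree}\t{row.rank}\n")
    return {"sif": sif, "edges": edge_path, "nodes": node_path}
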