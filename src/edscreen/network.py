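"""Molecular networking for activity-label propagation.

Nodes are compounds with a binary activity label for one assay; edges
connect pairs whose similarity meets a threshold, optionally filtered to
each node's top-k most similar partners (union over the two endpoints so
the edge set stays symmetric). A node's probability of activity is voted
from its direct neighbors, either by majority

    p = (number of active neighbors) / (number of neighbors)

or weighted by edge similarity

    p = sum of similarities to active neighbors / sum over all neighbors.

Isolated nodes receive no probability; they are carried as unconnected and
penalized by the modified ROC metrics. Evaluation is leave-one-out: the
topology is built once from the full similarity matrix, and each node is
scored from its neighbors' true labels only (its own label never enters
its prediction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .similarity import SimilarityMatrix

__all__ = [
    "NetworkConfig",
    "ActivityNetwork",
    "NodePrediction",
    "build_network",
    "vote",
    "loo_predict",
    "optimize_hyperparams",
]

VOTING_SCHEMES = ("majority", "weighted")


@dataclass(frozen=True)
class NetworkConfig:
    """Edge-construction and voting parameters for one network."""

    threshold: float = 0.5
    top_k: int | None = None
    voting: str = "majority"
    metric: str | None = None  # provenance tag for hyperparameter search

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.voting not in VOTING_SCHEMES:
            raise ValueError(f"unknown voting scheme {self.voting!r}")


@dataclass(frozen=True)
class NodePrediction:
    """Voted activity probability for one node; absent when unconnected."""

    compound_id: str
    probability: float | None
    connected: bool

    def __post_init__(self) -> None:
        if self.connected != (self.probability is not None):
            raise ValueError("probability must be present iff connected")


@dataclass
class ActivityNetwork:
    """Thresholded similarity graph with binary activity labels on nodes."""

    graph: nx.Graph
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def neighbors(self, node: str) -> list[tuple[str, float]]:
        return [(nb, self.graph.edges[node, nb]["weight"])
                for nb in self.graph.neighbors(node)]

    def write_edgelist(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(sep.join(["id_i", "id_j", "weight"]) + "\n")
            for i, j, w in sorted(self.graph.edges.data("weight")):
                a, b = sorted((i, j))
                fh.write(sep.join([a, b, f"{w:.6f}"]) + "\n")

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        nx.set_node_attributes(g, self.labels, "active")
        nx.write_graphml(g, path)


def build_network(matrix: SimilarityMatrix,
                  labels: Mapping[str, int],
                  config: NetworkConfig) -> ActivityNetwork:
    """Build the thresholded (and optionally top-k filtered) network.

    Only compounds with a binary label participate; inconclusive compounds
    must already be absent from ``labels``. An edge survives iff its weight
    is >= threshold and, when top-k filtering is on, at least one endpoint
    ranks the other among its k most similar passing neighbors (ties at the
    k-th similarity broken by ascending compound id).
    """
    ids = [i for i in matrix.ids if i in labels]
    if not ids:
        raise ValueError("no overlap between matrix ids and labels")
    idx = {c: matrix.ids.index(c) for c in ids}
    g = nx.Graph()
    g.add_nodes_from(ids)
    passing: dict[str, list[tuple[str, float]]] = {c: [] for c in ids}
    for a, b in itertools.combinations(ids, 2):
        w = float(matrix.values[idx[a], idx[b]])
        if w >= config.threshold:
            passing[a].append((b, w))
            passing[b].append((a, w))
    if config.top_k is None:
        for a in ids:
            for b, w in passing[a]:
                if a < b:
                    g.add_edge(a, b, weight=w)
    else:
        keep: set[tuple[str, str]] = set()
        for a in ids:
            ranked = sorted(passing[a], key=lambda t: (-t[1], t[0]))
            for b, _ in ranked[: config.top_k]:
                keep.add((min(a, b), max(a, b)))
        for a, b in keep:
            g.add_edge(a, b, weight=float(matrix.values[idx[a], idx[b]]))
    return ActivityNetwork(graph=g, labels={c: int(labels[c]) for c in ids})


def vote(node: str, net: ActivityNetwork, scheme: str = "majority") -> NodePrediction:
    """Voted probability of activity for one node from its neighbors."""
    if node not in net.graph:
        raise KeyError(f"unknown node {node!r}")
    if scheme not in VOTING_SCHEMES:
        raise ValueError(f"unknown voting scheme {scheme!r}")
    nbrs = net.neighbors(node)
    if not nbrs:
        return NodePrediction(node, None, False)
    if scheme == "majority":
        p = sum(net.labels[nb] for nb, _ in nbrs) / len(nbrs)
    else:
        total = sum(w for _, w in nbrs)
        if total == 0:  # all-zero weights (threshold 0): equal-weight vote
            p = sum(net.labels[nb] for nb, _ in nbrs) / len(nbrs)
        else:
            p = sum(w for nb, w in nbrs if net.labels[nb] == 1) / total
    return NodePrediction(node, float(p), True)


def loo_predict(matrix: SimilarityMatrix,
                labels: Mapping[str, int],
                config: NetworkConfig) -> list[NodePrediction]:
    """Leave-one-out predictions for every labeled node.

    The topology is built once; each node's probability uses only its
    neighbors' labels, which is exactly the leave-one-out estimate because
    a node's own label never contributes to its vote.
    """
    if sum(1 for i in matrix.ids if i in labels) < 2:
        raise ValueError("need at least 2 labeled nodes")
    net = build_network(matrix, labels, config)
    return [vote(node, net, config.voting) for node in net.nodes]


def optimize_hyperparams(
    matrix_by_metric: Mapping[str, SimilarityMatrix],
    labels: Mapping[str, int],
    grid: Sequence[NetworkConfig],
) -> list[tuple[NetworkConfig, float]]:
    """Score every (similarity metric, network config) combination by
    leave-one-out mROC-AUC and rank descending.

    Configs whose ``metric`` is set are evaluated against that matrix only;
    metric-less configs are crossed with every matrix. Ties are broken by
    (metric name, threshold ascending, voting name) for determinism.
    """
    from . import metrics as _metrics

    if not grid:
        raise ValueError("empty hyperparameter grid")
    results: list[tuple[NetworkConfig, float]] = []
    for cfg in grid:
        metric_names = [cfg.metric] if cfg.metric else sorted(matrix_by_metric)
        for name in metric_names:
            if name not in matrix_by_metric:
                raise KeyError(f"no similarity matrix for metric {name!r}")
            tagged = NetworkConfig(threshold=cfg.threshold, top_k=cfg.top_k,
                                   voting=cfg.voting, metric=name)
            preds = loo_predict(matrix_by_metric[name], labels, tagged)
            auc = _metrics.mroc_auc(preds, labels)
            results.append((tagged, auc))
    results.sort(key=lambda r: (-r[1], r[0].metric, r[0].threshold, r[0].voting))
    return results
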