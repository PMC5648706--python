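"""Patient-similarity networks.

Each patient is a vertex carrying their expression vector over a chosen gene
set; edge weights are Gaussian-kernel similarities ``exp(-d^2 / (2 sigma^2))``
and only the nearest neighbors of each vertex are linked (union-symmetrized),
so the network displays the cluster structure of infected vs aseptic tissue
rather than a dense hairball.

Distances are computed on the log-scaled feature space (the same
``ln(x + eps)`` + z-score transform the classifier networks use); raw-scale
distances would be dominated by the occasional patient with extreme
expression. ``sigma="auto"`` uses the median pairwise distance. A vertex's
``representativeness`` attribute is its final neighbor count (degree); the
optional density mode gives locally dense vertices proportionally more
neighbors.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .expression import CohortTable
from .mlp import FeatureScaling


def gaussian_similarity(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """``exp(-||x - y||^2 / (2 sigma^2))``; 1 at zero distance."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("vectors must not contain missing values")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def build_knn_graph(
    cohort: CohortTable,
    genes: Sequence[str],
    k: int = 3,
    sigma: float | str = "auto",
    mode: str = "uniform",
) -> nx.Graph:
    """Nearest-neighbor similarity graph over complete-case patients.

    Each vertex is linked to its k most-similar neighbors (ties broken by
    patient order) and the edge set is the union over vertices, so degrees
    can exceed k. ``mode="density"`` scales each vertex's neighbor count by
    its local density (inverse mean distance to its k nearest), a stand-in
    for degree-by-representativeness layouts. Node attributes: ``label`` and
    ``representativeness`` (final degree); edge attribute: ``weight``.
    """
    genes = list(genes)
    sub = cohort.complete_cases(genes)
    X = sub.matrix(genes)
    n = len(sub.patients)
    if n < 2:
        raise ValueError("need at least 2 complete-case patients")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n = {n}")
    if mode not in ("uniform", "density"):
        raise ValueError(f"unknown mode {mode!r}")

    Z = FeatureScaling.fit(X).transform(X)
    dist = squareform(pdist(Z))
    if sigma == "auto":
        sigma = float(np.median(squareform(dist, checks=False)))
        if sigma == 0:  # all points coincide
            sigma = 1.0
    elif not (isinstance(sigma, (int, float)) and sigma > 0):
        raise ValueError("sigma must be positive or 'auto'")

    if mode == "density":
        knn_dist = np.sort(dist, axis=1)[:, 1 : k + 1].mean(axis=1)
        inv = 1.0 / np.maximum(knn_dist, 1e-12)
        k_per = np.clip(np.round(k * inv / inv.mean()), 1, n - 1).astype(int)
    else:
        k_per = np.full(n, k)

    g = nx.Graph(sigma=float(sigma), k=int(k), mode=mode, genes=",".join(genes))
    ids = sub.patients
    for i, pid in enumerate(ids):
        g.add_node(pid, label=str(sub.labels.iloc[i]))
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbors = [j for j in order if j != i][: k_per[i]]
        for j in neighbors:
            w = float(np.exp(-dist[i, j] ** 2 / (2.0 * sigma**2)))
            g.add_edge(ids[i], ids[int(j)], weight=round(w, 6))
    for pid in g.nodes:
        g.nodes[pid]["representativeness"] = g.degree[pid]
    return g


def label_assortativity(g: nx.Graph) -> float:
    """Fraction of edges joining same-label vertices minus cross-label ones,
    in [-1, 1]; positive means classes cluster."""
    same = sum(1 for u, v in g.edges if g.nodes[u]["label"] == g.nodes[v]["label"])
    total = g.number_of_edges()
    if total == 0:
        return 0.0
    return (2 * same - total) / total


def export_graph(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or a TSV edge list (source, target, weight)."""
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{data['weight']:.6f}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            next(fh)
            for line in fh:
                u, v, w = line.rstrip("\n").split("\t")
                g.add_edge(u, v, weight=float(w))
        return g
    raise ValueError(f"unknown format {fmt!r}")
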