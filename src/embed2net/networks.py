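"""Cosine-similarity networks, component decomposition and control networks.

A similarity network connects two terms when the cosine of their vectors
reaches a threshold (closed bound: weight >= t), with the cosine kept as the
edge weight. Control constructions: a k-out random graph (every vertex draws
k partners with repetition, collapsed to a simple undirected graph), vertex
permutation (topology preserved, labels shuffled), and random edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .embedding import Embedding
from .errors import ParameterError, ParseError, SearchError


@dataclass
class SimilarityNetwork:
    graph: nx.Graph
    threshold: float | None = None
    weighted: bool = True

    @property
    def vertices(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.vertices
        return nx.to_numpy_array(self.graph, nodelist=order, weight="weight")

    def subnetwork(self, vertices: Sequence[str]) -> "SimilarityNetwork":
        keep = [v for v in self.vertices if v in set(vertices)]
        return SimilarityNetwork(self.graph.subgraph(keep).copy(),
                                 self.threshold, self.weighted)

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in self.graph.edges(data=True):
                w = data.get("weight", 1.0)
                fh.write(f"{u}\t{v}\t{w:.6g}\n")


@dataclass
class ComponentDecomposition:
    components: list[list[str]]  # each sorted; ordered by decreasing size

    @property
    def main(self) -> list[str]:
        return self.components[0]


@dataclass(frozen=True)
class ControlSpec:
    mode: str  # k_out_random | permute_vertices | random_weights
    k: int = 8
    weight_low: float = 0.65
    weight_high: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("k_out_random", "permute_vertices",
                             "random_weights"):
            raise ParameterError(f"unknown control mode {self.mode!r}")
        if self.k < 0:
            raise ParameterError("k must be >= 0")
        if self.weight_low > self.weight_high:
            raise ParameterError("weight interval must satisfy lo <= hi")


def build_similarity_network(embedding: Embedding, terms: Sequence[str],
                             t: float,
                             type_filter: str | None = None
                             ) -> SimilarityNetwork:
    """Graph over `terms` with an edge (u, v) iff cosine(u, v) >= t."""
    terms = list(dict.fromkeys(terms))
    if type_filter is not None:
        terms = [x for x in terms
                 if embedding.type_labels.get(x) == type_filter]
    idx = embedding.indices(terms)  # raises on unknown terms
    unit = embedding._unit_vectors()[idx]
    graph = nx.Graph()
    graph.add_nodes_from(terms)
    # chunk the gram matrix to bound memory on large vocabularies
    chunk = 1024
    n = len(terms)
    for start in range(0, n, chunk):
        block = np.clip(unit[start:start + chunk] @ unit.T, -1.0, 1.0)
        rows, cols = np.nonzero(block >= t)
        for r, c in zip(rows, cols):
            i = start + r
            if i < c:
                graph.add_edge(terms[i], terms[c], weight=float(block[r, c]))
    return SimilarityNetwork(graph, threshold=t, weighted=True)


def decompose(network: SimilarityNetwork) -> ComponentDecomposition:
    """Connected components, largest first; ties broken by smallest member."""
    comps = [sorted(c) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return ComponentDecomposition(comps)


def main_component(network: SimilarityNetwork) -> SimilarityNetwork:
    return network.subnetwork(decompose(network).main)


def threshold_for_size(embedding: Embedding, terms: Sequence[str],
                       target_vertices: int) -> tuple[float, int]:
    """Largest threshold whose main component reaches `target_vertices`.

    Scans the observed pairwise cosines in descending order, adding edges in
    ties together, until the largest component is big enough.
    """
    terms = list(dict.fromkeys(terms))
    if not 1 <= target_vertices <= len(terms):
        raise ParameterError("target_vertices out of range")
    sims = embedding.pairwise_cosines(terms)
    iu, ju = np.triu_indices(len(terms), k=1)
    weights = sims[iu, ju]
    order = np.argsort(-weights, kind="stable")
    # union-find over term indices
    parent = np.arange(len(terms))
    size = np.ones(len(terms), dtype=np.int64)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if target_vertices == 1:
        return float(weights.max()) if len(weights) else 1.0, 1
    best = 1
    pos = 0
    while pos < len(order):
        w = weights[order[pos]]
        # merge every edge tied at weight w
        while pos < len(order) and weights[order[pos]] == w:
            e = order[pos]
            a, b = find(iu[e]), find(ju[e])
            if a != b:
                if size[a] < size[b]:
                    a, b = b, a
                parent[b] = a
                size[a] += size[b]
                best = max(best, size[a])
            pos += 1
        if best >= target_vertices:
            return float(w), int(best)
    raise SearchError(
        f"main component never reaches {target_vertices} vertices; "
        f"best achievable is {best}")


def make_control_network(reference: SimilarityNetwork | int,
                         spec: ControlSpec) -> SimilarityNetwork:
    """Build one of the three control networks (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "k_out_random":
        n = reference.n_vertices if isinstance(reference, SimilarityNetwork) \
            else int(reference)
        if spec.k >= n:
            raise ParameterError("k must be smaller than the vertex count")
        names = (reference.vertices if isinstance(reference, SimilarityNetwork)
                 else [f"v{i}" for i in range(n)])
        graph = nx.Graph()
        graph.add_nodes_from(names)
        # each vertex draws k partners uniformly from the others, with
        # repetition; duplicate and reciprocal draws collapse
        draws = rng.integers(0, n - 1, size=(n, spec.k))
        for i in range(n):
            for d in draws[i]:
                j = d if d < i else d + 1  # skip self
                graph.add_edge(names[i], names[j], weight=1.0)
        return SimilarityNetwork(graph, threshold=None, weighted=False)

    if not isinstance(reference, SimilarityNetwork):
        raise ParameterError(f"mode {spec.mode} needs a reference network")
    if spec.mode == "permute_vertices":
        names = reference.vertices
        perm = rng.permutation(len(names))
        mapping = {names[i]: names[perm[i]] for i in range(len(names))}
        graph = nx.relabel_nodes(reference.graph, mapping, copy=True)
        return SimilarityNetwork(graph, reference.threshold,
                                 reference.weighted)
    # random_weights
    graph = reference.graph.copy()
    for u, v in graph.edges:
        graph[u][v]["weight"] = float(
            rng.uniform(spec.weight_low, spec.weight_high))
    return SimilarityNetwork(graph, reference.threshold, weighted=True)


def import_weighted_edges(path: str | Path, t: float) -> SimilarityNetwork:
    """Read a TSV edge list, keep weights >= t, drop self-loops, and keep the
    maximum weight of duplicate pairs."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected 3 tab-separated "
                                 f"fields, got {len(parts)}")
            a, b = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric weight {parts[2]!r}") from None
            if a == b:
                continue
            if w >= t:
                if graph.has_edge(a, b):
                    graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
                else:
                    graph.add_edge(a, b, weight=w)
    return SimilarityNetwork(graph, threshold=t, weighted=True)


def degree_statistics(network: SimilarityNetwork) -> dict[str, float]:
    """Mean, median and standard deviation of the degree distribution."""
    degrees = np.array([d for _, d in network.graph.degree()], dtype=float)
    return {"mean": float(degrees.mean()),
            "median": float(np.median(degrees)),
            "sd": float(degrees.std(ddof=0))}
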