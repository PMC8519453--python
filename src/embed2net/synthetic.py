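"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators:

* a corpus of short documents with planted entity co-occurrence groups and
  synonym variants — each document is "about" one gene group, disease group
  or drug, mentions its entities together (as a contiguous block, so a
  window-based embedding trainer sees the co-occurrence), and sprinkles
  off-topic entities at a low background rate;
* a knowledgebase consistent with the planted groups: GMT group files, a
  PPI list of within-group pairs, and drug->target assignments constructed
  so drug pairs realize the 0 / 1-5 / 6-9 shared-target strata;
* a graph-structured expression matrix with two imbalanced classes where
  class 1 carries a mean shift on a connected signal subnetwork, decaying
  exponentially with hop distance from a seed vertex.

Rate semantics: ``within_rate`` is the probability that two same-group
entities co-occur in a document about their group (each member is included
independently with probability sqrt(within_rate)); ``background_rate`` is
the per-document mention probability of any off-topic entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import TextDocument
from .errors import SpecError
from .networks import SimilarityNetwork


@dataclass(frozen=True)
class CorpusSpec:
    n_gene_groups: int = 10
    gene_group_size: int = 10
    n_disease_groups: int = 4
    disease_group_size: int = 5
    n_drugs: int = 20
    n_documents: int = 2000
    doc_length_mean: float = 40.0
    background_vocab: int = 500
    within_rate: float = 0.3
    background_rate: float = 0.01
    synonym_variants: int = 2
    synonym_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for rate in (self.within_rate, self.background_rate,
                     self.synonym_prob):
            if not 0 <= rate <= 1:
                raise SpecError("rates must lie in [0, 1]")
        if self.within_rate <= self.background_rate:
            raise SpecError("within_rate must exceed background_rate")
        if self.n_gene_groups * self.gene_group_size < 1:
            raise SpecError("need at least one gene")


@dataclass
class CorpusTruth:
    """Planted structure: groups, synonym map, drug targets."""
    gene_groups: dict[str, list[str]]
    disease_groups: dict[str, list[str]]
    drugs: list[str]
    drug_targets: dict[str, list[str]]
    synonyms: dict[str, tuple[str, str]]   # variant phrase -> (preferred, type)
    entity_types: dict[str, str]           # preferred token -> type

    def synonym_rows(self) -> list[tuple[str, str, str]]:
        """(preferred_term, synonym, entity_type) rows incl. identity rows."""
        rows = []
        seen = set()
        for preferred_token, etype in self.entity_types.items():
            preferred = preferred_token.replace("_", " ")
            rows.append((preferred, preferred, etype))
            seen.add(preferred)
        for variant, (preferred, etype) in self.synonyms.items():
            if variant not in seen:
                rows.append((preferred, variant, etype))
        return rows

    def ppi_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for members in self.gene_groups.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = sorted((members[i], members[j]))
                    pairs.append((a, b))
        return sorted(set(pairs))


def _entity_names(spec: CorpusSpec):
    n_genes = spec.n_gene_groups * spec.gene_group_size
    genes = [f"g{i:03d}" for i in range(n_genes)]
    diseases = [f"d{i:02d} syndrome"
                for i in range(spec.n_disease_groups * spec.disease_group_size)]
    drugs = [f"drug{i:02d}" for i in range(spec.n_drugs)]
    return genes, diseases, drugs


def _variants(name: str, etype: str, k: int) -> list[str]:
    base = name.replace(" ", "")
    out = []
    for j in range(k):
        if etype == "disease" and j == 0:
            out.append(name.split()[0] + " disorder")   # multi-word variant
        else:
            out.append(f"{base}{'abcdefgh'[j]}")
    return out


def _drug_target_sets(spec: CorpusSpec,
                      gene_groups: dict[str, list[str]]) -> dict[str, list[str]]:
    """Two drugs per gene group; same-group pairs share 6 (even groups) or 3
    (odd groups) targets, cross-group pairs share none."""
    group_ids = sorted(gene_groups)
    targets = {}
    for i in range(spec.n_drugs):
        gid = group_ids[(i // 2) % len(group_ids)]
        members = gene_groups[gid]
        if i % 2 == 0:
            targets[f"drug{i:02d}"] = members[:8]
        elif ((i // 2) % 2) == 0:
            targets[f"drug{i:02d}"] = members[2:10]   # shares 6 with partner
        else:
            targets[f"drug{i:02d}"] = members[5:10]   # shares 3 with partner
    return targets


def generate_corpus(spec: CorpusSpec = CorpusSpec()
                    ) -> tuple[list[TextDocument], CorpusTruth]:
    """Emit documents plus the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    genes, diseases, drugs = _entity_names(spec)
    gene_groups = {
        f"gene_group_{g:02d}":
            genes[g * spec.gene_group_size:(g + 1) * spec.gene_group_size]
        for g in range(spec.n_gene_groups)}
    disease_groups = {
        f"disease_group_{g:02d}":
            diseases[g * spec.disease_group_size:
                     (g + 1) * spec.disease_group_size]
        for g in range(spec.n_disease_groups)}
    drug_targets = _drug_target_sets(spec, gene_groups)

    entity_types = {}
    synonyms = {}
    variants_of: dict[str, list[str]] = {}
    for name, etype in ([(g, "gene") for g in genes]
                        + [(d, "disease") for d in diseases]
                        + [(d, "drug") for d in drugs]):
        token = "_".join(name.split())
        entity_types[token] = etype
        forms = _variants(name, etype, spec.synonym_variants)
        variants_of[name] = forms
        for form in forms:
            synonyms[form] = (name, etype)

    # background vocabulary with Zipf-like weights
    vocab = [f"w{i:03d}" for i in range(spec.background_vocab)]
    weights = 1.0 / np.arange(1, spec.background_vocab + 1)
    weights /= weights.sum()

    q = float(np.sqrt(spec.within_rate))
    bg = spec.background_rate
    all_entities = ([(g, "gene") for g in genes]
                    + [(d, "disease") for d in diseases]
                    + [(d, "drug") for d in drugs])

    def emit(name: str) -> list[str]:
        forms = variants_of[name]
        if forms and spec.synonym_prob > 0 and rng.random() < spec.synonym_prob:
            form = forms[rng.integers(0, len(forms))]
        else:
            form = name
        return form.split()

    gene_ids = sorted(gene_groups)
    disease_ids = sorted(disease_groups)
    documents = []
    for d in range(spec.n_documents):
        u = rng.random()
        mentions: list[str] = []
        if u < 0.7:                      # gene-group document
            members = gene_groups[gene_ids[rng.integers(0, len(gene_ids))]]
            topic = set(members)
            for m in members:
                if rng.random() < q:
                    mentions.extend(emit(m))
        elif u < 0.9 and disease_ids:    # disease-group document
            members = disease_groups[
                disease_ids[rng.integers(0, len(disease_ids))]]
            topic = set(members)
            for m in members:
                if rng.random() < q:
                    mentions.extend(emit(m))
        else:                            # drug document
            drug = drugs[rng.integers(0, len(drugs))] if drugs else None
            topic = {drug} if drug else set()
            if drug:
                mentions.extend(emit(drug))
                for gene in drug_targets.get(drug, []):
                    if rng.random() < 0.3:
                        mentions.extend(emit(gene))
        for name, _etype in all_entities:
            if name not in topic and rng.random() < bg:
                mentions.extend(emit(name))
        length = max(10, int(rng.poisson(spec.doc_length_mean)))
        background = list(rng.choice(vocab, size=length, p=weights))
        mention_perm = rng.permutation(len(mentions))
        block = [mentions[i] for i in mention_perm]
        pos = int(rng.integers(0, length + 1))
        tokens = background[:pos] + block + background[pos:]
        documents.append(TextDocument(f"doc{d}", " ".join(tokens)))

    truth = CorpusTruth(gene_groups, disease_groups, list(drugs),
                        drug_targets, synonyms, entity_types)
    return documents, truth


def write_corpus(path: str | Path, documents: list[TextDocument]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(doc.text + "\n")


def write_synonym_table(path: str | Path, truth: CorpusTruth) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("preferred_term\tsynonym\tentity_type\n")
        for preferred, synonym, etype in truth.synonym_rows():
            fh.write(f"{preferred}\t{synonym}\t{etype}\n")


def generate_knowledgebase(truth: CorpusTruth,
                           out_dir: str | Path) -> dict[str, Path]:
    """Write GMT group files, a PPI TSV and a drug-target TSV from the
    planted ground truth; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def token(name: str) -> str:
        return "_".join(name.split())

    gmt = out_dir / "gene_groups.gmt"
    with open(gmt, "w", encoding="utf-8") as fh:
        for gid, members in sorted(truth.gene_groups.items()):
            fh.write("\t".join([gid, "planted"] + members) + "\n")
    paths["gene_groups"] = gmt

    dg = out_dir / "disease_groups.gmt"
    with open(dg, "w", encoding="utf-8") as fh:
        for gid, members in sorted(truth.disease_groups.items()):
            fh.write("\t".join([gid, "planted"]
                               + [token(m) for m in members]) + "\n")
    paths["disease_groups"] = dg

    ppi = out_dir / "ppi_pairs.tsv"
    with open(ppi, "w", encoding="utf-8") as fh:
        for a, b in truth.ppi_pairs():
            fh.write(f"{a}\t{b}\n")
    paths["ppi"] = ppi

    dt = out_dir / "drug_targets.tsv"
    with open(dt, "w", encoding="utf-8") as fh:
        for drug in sorted(truth.drug_targets):
            for gene in truth.drug_targets[drug]:
                fh.write(f"{drug}\t{gene}\n")
    paths["drug_targets"] = dt
    return paths


@dataclass
class ExpressionSpec:
    network: SimilarityNetwork
    n_samples: int = 300
    class1_fraction: float = 0.4     # minority class, emulating 393:576
    signal_size: int = 30
    effect: float = 2.0              # mean shift in noise-sd units
    noise_sd: float = 1.0
    decay_rate: float = 0.5          # per-hop exponential attenuation
    seed: int = 1

    def __post_init__(self):
        if self.effect < 0:
            raise SpecError("effect size must be >= 0")
        if not 0 < self.class1_fraction < 1:
            raise SpecError("class1_fraction must be in (0, 1)")
        if self.signal_size > self.network.n_vertices:
            raise SpecError("signal subnetwork larger than the network")


def generate_expression(spec: ExpressionSpec
                        ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Graph-smooth two-class expression data.

    Returns (matrix samples x genes, binary labels, signal gene list). The
    signal subnetwork is the breadth-first neighborhood of a seed vertex,
    guaranteed connected; class-1 samples receive a mean shift of
    effect * noise_sd * exp(-decay_rate * hops) on those genes. The matrix
    is shifted so its global minimum is zero.
    """
    rng = np.random.default_rng(spec.seed)
    graph = spec.network.graph
    vertices = spec.network.vertices
    if not nx.is_connected(graph):
        raise SpecError("prior network must be connected")
    seed_vertex = vertices[rng.integers(0, len(vertices))]
    hops = nx.single_source_shortest_path_length(graph, seed_vertex)
    bfs_order = sorted(hops, key=lambda v: (hops[v], v))
    signal = bfs_order[:spec.signal_size]
    if len(signal) < spec.signal_size:
        raise SpecError("could not grow a connected signal subnetwork")

    shift = np.zeros(len(vertices))
    index = {v: i for i, v in enumerate(vertices)}
    for v in signal:
        shift[index[v]] = (spec.effect * spec.noise_sd
                           * np.exp(-spec.decay_rate * hops[v]))

    n1 = int(round(spec.n_samples * spec.class1_fraction))
    y = np.zeros(spec.n_samples, dtype=int)
    y[:n1] = 1
    rng.shuffle(y)
    X = rng.normal(0.0, spec.noise_sd,
                   size=(spec.n_samples, len(vertices)))
    X[y == 1] += shift[None, :]
    X -= X.min()
    samples = [f"s{i:03d}" for i in range(spec.n_samples)]
    matrix = pd.DataFrame(X, index=samples, columns=vertices)
    labels = pd.Series(y, index=samples)
    return matrix, labels, signal


def watts_strogatz_prior(n: int = 500, k: int = 6, p: float = 0.1,
                         seed: int = 0) -> SimilarityNetwork:
    """Connected small-world graph usable as a synthetic prior network."""
    graph = nx.connected_watts_strogatz_graph(n, k, p, seed=seed)
    relabeled = nx.relabel_nodes(graph, {i: f"g{i:03d}" for i in graph.nodes})
    for u, v in relabeled.edges:
        relabeled[u][v]["weight"] = 1.0
    return SimilarityNetwork(relabeled, threshold=None, weighted=False)
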