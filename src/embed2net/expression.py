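"""Expression-matrix preparation for graph-structured learning.

Implements the bespoke rules applied downstream of standard microarray
normalization: collapsing multiple probes per gene to the probe with the
highest average expression, shifting the matrix so its global minimum is
zero, and aligning features to the vertex order of a prior network's main
connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParameterError
from .networks import SimilarityNetwork, decompose

log = logging.getLogger(__name__)


@dataclass
class GraphAlignedDataset:
    """Expression features ordered by graph vertices, with binary labels."""
    X: np.ndarray              # samples x vertices
    y: np.ndarray              # {0, 1}
    genes: list[str]           # == aligned network vertex order
    samples: list[str]
    graph: SimilarityNetwork   # connected subnetwork the columns follow

    def __post_init__(self):
        if self.X.shape != (len(self.samples), len(self.genes)):
            raise ParameterError("matrix shape does not match labels/genes")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ParameterError("labels must be binary")


def read_expression(path: str | Path, orientation: str = "auto"
                    ) -> pd.DataFrame:
    """Read a TSV/CSV expression matrix into samples x features.

    With orientation="auto", the matrix is transposed when it has more rows
    than columns (features usually outnumber samples); the decision is logged.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features_rows" or (
            orientation == "auto" and df.shape[0] > df.shape[1]):
        log.info("read_expression: transposing %s (rows look like features)",
                 path)
        df = df.T
    return df


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"])
    return pd.Series(df["label"].astype(int).values, index=df["sample"])


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"])
    return dict(zip(df["probe"], df["gene"]))


def collapse_probes(matrix: pd.DataFrame,
                    probe_map: Mapping[str, str]) -> pd.DataFrame:
    """One column per gene: the probe with the highest across-sample mean.

    Ties are broken by the lexicographically smallest probe identifier.
    Retained measurement values are untouched.
    """
    unmapped = [p for p in matrix.columns if p not in probe_map]
    if unmapped:
        raise ParameterError(f"probes missing from the map: {unmapped[:10]}")
    means = matrix.mean(axis=0)
    chosen: dict[str, str] = {}
    for probe in sorted(matrix.columns):  # lexicographic tie-break
        gene = probe_map[probe]
        cur = chosen.get(gene)
        if cur is None or means[probe] > means[cur]:
            chosen[gene] = probe
    genes = sorted(chosen)
    out = matrix[[chosen[g] for g in genes]].copy()
    out.columns = genes
    return out


def nonnegative_shift(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract the global minimum from every cell; output minimum is 0."""
    if matrix.size == 0:
        raise ParameterError("matrix is empty")
    return matrix - matrix.values.min()


def align_to_graph(matrix: pd.DataFrame, network: SimilarityNetwork,
                   labels: pd.Series) -> GraphAlignedDataset:
    """Restrict features to network vertices and order them by the graph.

    The matrix genes are intersected with the network vertices, the main
    connected component of the induced subgraph is re-extracted, and columns
    are reordered to that component's vertex order.
    """
    missing = [s for s in matrix.index if s not in labels.index]
    if missing:
        raise ParameterError(f"labels missing for samples: {missing[:10]}")
    shared = [v for v in network.vertices if v in set(matrix.columns)]
    if not shared:
        raise AlignmentError("no gene shared between matrix and network")
    induced = network.subnetwork(shared)
    comp = decompose(induced).main
    aligned = induced.subnetwork(comp)
    order = aligned.vertices
    log.info("align_to_graph: %d matrix genes, %d network vertices, "
             "%d shared, %d in aligned main component",
             matrix.shape[1], network.n_vertices, len(shared), len(order))
    X = matrix[order].to_numpy(dtype=float)
    y = labels.loc[matrix.index].to_numpy(dtype=int)
    return GraphAlignedDataset(X, y, order, list(matrix.index), aligned)
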