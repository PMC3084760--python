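"""Similarity-network export and per-cluster statistics.

The network view of a reference set has one node per sequence (annotated
with its type) and one weighted edge per sequence pair whose percent
similarity clears a threshold.  No layout is computed here — the graph is
exported (TSV edge list / GraphML) for external viewers.
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .alignment import SimilarityMatrix
from .records import EnzymeType


def build_network(simmatrix: SimilarityMatrix, labels: Mapping[str, EnzymeType],
                  min_edge: float = 0.0) -> nx.Graph:
    """Weighted similarity graph: edges for pairs with similarity >= min_edge.

    Zero-similarity pairs never get an edge; self-pairs are excluded.
    Node attribute ``type`` holds the enzyme-type label.
    """
    graph = nx.Graph()
    for record_id in simmatrix.ids:
        label = labels.get(record_id)
        graph.add_node(record_id, type=label.value if label else "")
    n = len(simmatrix.ids)
    for i, j in itertools.combinations(range(n), 2):
        weight = float(simmatrix.sim[i, j])
        if weight > 0 and weight >= min_edge:
            graph.add_edge(simmatrix.ids[i], simmatrix.ids[j], weight=weight)
    return graph


def cluster_mean_similarity(simmatrix: SimilarityMatrix,
                            labels: Mapping[str, EnzymeType],
                            ) -> dict[tuple[EnzymeType, EnzymeType], float]:
    """Arithmetic mean pairwise similarity within and between type clusters.

    Within-type means run over unordered distinct pairs; cross-type means
    over all pairs with one member in each type.  A type with fewer than
    two members has an undefined (NaN) within-type mean.
    """
    unlabeled = [i for i in simmatrix.ids if i not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled ids in similarity matrix: {unlabeled[:5]}")
    types = sorted({labels[i] for i in simmatrix.ids}, key=lambda t: t.value)
    index = {t: np.array([k for k, i in enumerate(simmatrix.ids) if labels[i] is t])
             for t in types}
    means: dict[tuple[EnzymeType, EnzymeType], float] = {}
    for a, b in itertools.combinations_with_replacement(types, 2):
        ia, ib = index[a], index[b]
        if a is b:
            if len(ia) < 2:
                means[(a, a)] = math.nan
                continue
            block = simmatrix.sim[np.ix_(ia, ia)]
            upper = block[np.triu_indices(len(ia), k=1)]
            means[(a, a)] = float(upper.mean())
        else:
            means[(a, b)] = float(simmatrix.sim[np.ix_(ia, ib)].mean())
    return means


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list: id1, id2, similarity."""
    with open(path, "w") as handle:
        handle.write("id1\tid2\tsimilarity\n")
        for u, v, data in sorted(graph.edges(data=True)):
            handle.write(f"{u}\t{v}\t{data['weight']:.4f}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export (node ``type`` and edge ``weight`` attributes kept)."""
    nx.write_graphml(graph, str(path))
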