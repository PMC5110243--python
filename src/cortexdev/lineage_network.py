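"""Thresholded intercellular correlation networks and MST pseudotime.

Lineage structure in a progenitor-to-neuron continuum shows up as the
topology of a simple graph: cells are vertices and two cells are connected
when the Pearson correlation of their transcriptomes (over an informative
gene subset) exceeds a threshold (0.4 in the study this follows). As an
independent corroboration, a minimum spanning tree is built on the complete
graph with distance 1 - r; its diameter (the longest shortest path) is a
backbone along which cells are ordered, giving a pseudotime up to global
reversal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.4


@dataclass
class LineageGraph:
    """Undirected cell graph; edge weights are Pearson correlations > tau."""

    graph: nx.Graph
    tau: float

    def write_edge_list(self, path) -> None:
        rows = [
            {"cell_i": u, "cell_j": v, "weight": d["weight"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["cell_i", "cell_j", "weight"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class PseudotimeOrder:
    """Cells ordered along the MST backbone with projected positions.

    ``positions`` is the cumulative backbone distance of each cell's
    attachment node; the ordering is meaningful up to global reversal.
    """

    order: list[str]
    positions: pd.Series

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {"cell_id": self.order, "position": [self.positions[c] for c in self.order]}
        ).to_csv(path, index=False)


def _pearson_matrix(m: ExpressionMatrix, genes: Sequence[str] | None) -> tuple[np.ndarray, list[str]]:
    """Cell-cell Pearson correlations over a gene subset; drops constant cells."""
    m.require_log()
    if genes is None:
        subset = m.gene_ids
    else:
        subset = [g for g in genes if g in m.values.columns]
        if not subset:
            raise ValueError("no requested gene present in the matrix")
    x = m.values[subset].to_numpy(dtype=float)
    ok = np.std(x, axis=1) > 0
    dropped = [c for c, keep in zip(m.cell_ids, ok) if not keep]
    if dropped:
        logger.warning("excluding %d constant cells: %s", len(dropped), dropped[:5])
    ids = [c for c, keep in zip(m.cell_ids, ok) if keep]
    corr = np.corrcoef(x[ok]) if ok.sum() > 1 else np.ones((ok.sum(), ok.sum()))
    return corr, ids


def build_network(
    m: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    tau: float = DEFAULT_TAU,
) -> LineageGraph:
    """Connect cells whose pairwise Pearson correlation exceeds ``tau``.

    Correlations are computed over ``genes`` (default: all genes). Cells
    constant over the subset are excluded from the graph with a warning.
    """
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    corr, ids = _pearson_matrix(m, genes)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if corr[i, j] > tau:
                g.add_edge(ids[i], ids[j], weight=float(corr[i, j]))
    return LineageGraph(graph=g, tau=tau)


def _tree_diameter_path(tree: nx.Graph) -> list[str]:
    """Longest weighted shortest path of a tree, via two Dijkstra sweeps.

    Ties at the farthest node resolve to the smallest node id, making the
    backbone deterministic.
    """

    def farthest(source):
        dist = nx.single_source_dijkstra_path_length(tree, source, weight="weight")
        best = max(dist.values())
        return min(n for n, d in dist.items() if np.isclose(d, best))

    start = min(tree.nodes)
    u = farthest(start)
    v = farthest(u)
    a, b = sorted((u, v))
    return nx.shortest_path(tree, a, b, weight="weight")


def mst_pseudotime(
    m: ExpressionMatrix,
    genes: Sequence[str] | None = None,
) -> PseudotimeOrder:
    """Order cells along the diameter of a minimum spanning tree.

    The complete graph over cells with distance 1 - Pearson r (over the
    gene subset) is reduced to its MST; equal-weight edges resolve by
    lexicographic cell-id pair. The tree diameter forms the backbone; every
    other cell is projected to its nearest backbone node (tree-path
    distance) and inherits that node's cumulative backbone position. Cells
    are returned sorted by position, then id.
    """
    corr, ids = _pearson_matrix(m, genes)
    if len(ids) == 0:
        raise ValueError("no usable cells")
    if len(ids) == 1:
        return PseudotimeOrder(order=list(ids), positions=pd.Series(0.0, index=ids))

    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(ids)):  # lexicographic insertion; Kruskal sorts stably
        for j in range(i + 1, len(ids)):
            g.add_edge(ids[i], ids[j], weight=float(1.0 - corr[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="weight", algorithm="kruskal")

    components = list(nx.connected_components(mst))
    if len(components) > 1:  # cannot happen from a complete graph; guard anyway
        logger.warning("MST disconnected: ordering %d components separately", len(components))

    order: list[str] = []
    positions: dict[str, float] = {}
    pos_offset = 0.0
    for comp in sorted(components, key=lambda c: min(c)):
        sub = mst.subgraph(comp)
        backbone = _tree_diameter_path(sub) if len(comp) > 1 else [next(iter(comp))]
        cum = {backbone[0]: 0.0}
        for a, b in zip(backbone, backbone[1:]):
            cum[b] = cum[a] + sub[a][b]["weight"]
        # nearest backbone node by tree-path distance
        dist_to_backbone, source_of = nx.multi_source_dijkstra(
            sub, set(backbone), weight="weight"
        )
        comp_pos = {}
        for node in comp:
            attach = source_of[node][0] if isinstance(source_of[node], list) else source_of[node]
            comp_pos[node] = cum[attach]
        del dist_to_backbone
        comp_order = sorted(comp, key=lambda n: (comp_pos[n], n))
        order.extend(comp_order)
        for n in comp:
            positions[n] = pos_offset + comp_pos[n]
        if len(backbone) > 1:
            pos_offset += cum[backbone[-1]] + 1.0
    return PseudotimeOrder(order=order, positions=pd.Series(positions).loc[order])
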