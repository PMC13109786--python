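"""Residue contact graphs.

Nodes are residues carrying their 5-dim physicochemical feature vector;
an undirected edge connects two residues whenever their Calpha-Calpha
Euclidean distance is strictly below the cutoff (default 9.5 A). Each edge
stores its exact distance. For a connected polypeptide chain (consecutive
Calpha spacing ~3.8 A) every consecutive residue pair is therefore an edge,
so the backbone is always part of the graph.

Edges are stored once with i < j and expanded to both directions at model
time. For large structures a k-d tree prunes the candidate pairs, but the
retained edge set is decided by exactly the same distance expression as the
brute-force rule, so both paths agree bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import GraphError
from .features import PropertyTable, default_property_table, encode_residues

#: number of residues above which the k-d tree pruning kicks in
_KDTREE_MIN_N = 500


@dataclass(frozen=True)
class GraphConfig:
    """Contact-graph construction parameters."""

    cutoff: float = 9.5          # Angstrom, strict upper bound on edge length
    include_self_loops: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise GraphError(f"cutoff must be positive, got {self.cutoff}")


@dataclass
class ResidueGraph:
    """Contact graph of one protein."""

    protein_id: str
    node_features: np.ndarray   # (n, 5) in [0, 1]
    coords: np.ndarray          # (n, 3) Angstrom
    edges: np.ndarray           # (m, 2) int, i < j, lexicographically sorted
    distances: np.ndarray       # (m,) Angstrom
    residue_labels: list[str]   # code + seq_index tokens, length n
    cutoff: float = 9.5

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg


def _pair_distances(coords: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    # the single distance expression shared by both search strategies
    d = coords[i] - coords[j]
    return np.sqrt((d * d).sum(axis=1))


def contact_edges(coords: np.ndarray, cutoff: float):
    """All pairs (i < j) with Euclidean distance strictly below ``cutoff``.

    Returns ``(edges, distances)`` with edges sorted lexicographically.
    """
    n = coords.shape[0]
    if n <= _KDTREE_MIN_N:
        iu, ju = np.triu_indices(n, k=1)
    else:
        # prune with a k-d tree; final decision uses the shared expression
        pairs = cKDTree(coords).query_pairs(cutoff * 1.0000001, output_type="ndarray")
        if pairs.size == 0:
            return np.empty((0, 2), dtype=int), np.empty(0)
        iu, ju = np.minimum(pairs[:, 0], pairs[:, 1]), np.maximum(pairs[:, 0], pairs[:, 1])
    dist = _pair_distances(coords, iu, ju)
    keep = dist < cutoff
    edges = np.column_stack([iu[keep], ju[keep]])
    dist = dist[keep]
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order], dist[order]


def build_graph(structure, table: PropertyTable | None = None,
                config: GraphConfig = GraphConfig()) -> ResidueGraph:
    """Build the contact graph of a structure."""
    if len(structure) < 2:
        raise GraphError(f"{structure.protein_id}: need at least 2 residues")
    if table is None:
        table = default_property_table()
    features = encode_residues(structure, table)
    coords = structure.ca_coords
    edges, dist = contact_edges(coords, config.cutoff)
    return ResidueGraph(
        protein_id=structure.protein_id,
        node_features=features,
        coords=coords,
        edges=edges,
        distances=dist,
        residue_labels=structure.labels,
        cutoff=config.cutoff,
    )


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    mean_degree: float
    n_components: int


def graph_summary(graph: ResidueGraph) -> GraphSummary:
    """Node/edge counts, mean degree and connected-component count."""
    n = graph.n_nodes
    m = graph.n_edges
    if m:
        adj = coo_matrix(
            (np.ones(m), (graph.edges[:, 0], graph.edges[:, 1])), shape=(n, n)
        )
        n_comp, _ = connected_components(adj, directed=False)
    else:
        n_comp = n
    return GraphSummary(
        n_nodes=n, n_edges=m, mean_degree=2.0 * m / n, n_components=int(n_comp)
    )


def save_graph(graph: ResidueGraph, path) -> None:
    """Cache a graph as a portable .npz container."""
    np.savez_compressed(
        path,
        protein_id=np.array(graph.protein_id),
        node_features=graph.node_features,
        coords=graph.coords,
        edges=graph.edges,
        distances=graph.distances,
        residue_labels=np.array(graph.residue_labels),
        cutoff=np.array(graph.cutoff),
    )


def load_graph(path) -> ResidueGraph:
    with np.load(path, allow_pickle=False) as z:
        return ResidueGraph(
            protein_id=str(z["protein_id"]),
            node_features=z["node_features"],
            coords=z["coords"],
            edges=z["edges"],
            distances=z["distances"],
            residue_labels=[str(s) for s in z["residue_labels"]],
            cutoff=float(z["cutoff"]),
        )
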