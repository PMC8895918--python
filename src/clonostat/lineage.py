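"""Clonal-lineage network inference from CDR3 nucleotide clonotypes.

Somatic hypermutation produces clusters of near-identical CDR3 nt
sequences. Clonotypes sharing V gene, J gene and CDR3 nt length are
grouped; within each group, pairs at >= 95% positional nucleotide
identity are linked, and the connected components of the resulting
graph with at least two members are the clonal lineages. The
nearest-neighbor identity distribution over (CDR3 length, % identity)
is the calibration that motivates the 95% cut-off: genuine mutants pile
up at >= 95% while unrelated same-length sequences sit near ~55-90%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

#: comparisons against the identity threshold use this slack so exact
#: boundary ratios (e.g. 19/20 == 95%) are never lost to rounding
IDENTITY_TOL = 1e-9

NodeKey = tuple[str, str, str]  # (v_gene, j_gene, cdr3_nt)


def identity_pct(a: str, b: str) -> float:
    """Percent of identical positions between two equal-length nt strings."""
    if len(a) != len(b):
        raise ValueError("identity is undefined for unequal lengths")
    if not a:
        raise ValueError("identity of empty sequences is undefined")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


@dataclass
class VJLGroup:
    """Distinct CDR3 nt clonotypes sharing (V gene, J gene, CDR3 length)."""

    key: tuple[str, str, int]
    seqs: list[str]
    counts: np.ndarray

    def __len__(self) -> int:
        return len(self.seqs)


def collapse_nt_clonotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate clone rows to distinct (V, J, CDR3 nt) clonotypes."""
    out = (
        df.groupby(["v_gene", "j_gene", "cdr3_nt"], as_index=False)["count"]
        .sum()
        .sort_values(["v_gene", "j_gene", "cdr3_nt"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def group_by_vjl(df: pd.DataFrame) -> list[VJLGroup]:
    """Partition distinct nt clonotypes into (V, J, length) groups.

    The partition is exhaustive and disjoint; singleton groups are kept
    (they simply contribute no neighbors or edges).
    """
    collapsed = collapse_nt_clonotypes(df)
    collapsed["cdr3_len"] = collapsed["cdr3_nt"].str.len()
    groups = []
    for (v, j, length), sub in collapsed.groupby(["v_gene", "j_gene", "cdr3_len"], sort=True):
        groups.append(
            VJLGroup(
                key=(str(v), str(j), int(length)),
                seqs=sub["cdr3_nt"].tolist(),
                counts=sub["count"].to_numpy(),
            )
        )
    return groups


def _identity_matrix(seqs: list[str]) -> np.ndarray:
    """All-pairs percent identity for equal-length sequences."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    matches = (arr[:, None, :] == arr[None, :, :]).sum(axis=2)
    return 100.0 * matches / arr.shape[1]


def nearest_neighbor(group: VJLGroup) -> dict[str, float]:
    """Highest identity of each member to any other member of its group.

    Singleton groups have no neighbors and yield an empty map.
    """
    if len(group) < 2:
        return {}
    ident = _identity_matrix(group.seqs)
    np.fill_diagonal(ident, -np.inf)
    best = ident.max(axis=1)
    return {seq: float(b) for seq, b in zip(group.seqs, best)}


def nn_distribution(df: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """2D histogram of clonotypes over (CDR3 nt length, NN identity bin).

    Counts unique clonotypes that have at least one same-group
    companion. Bins are ``bin_width``-percent wide on [0, 100] with the
    last bin closed at 100. Columns: cdr3_length, identity_bin (left
    edge), n_clonotypes.
    """
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    rows = []
    for group in group_by_vjl(df):
        nn = nearest_neighbor(group)
        if not nn:
            continue
        vals = np.fromiter(nn.values(), dtype=float)
        hist, _ = np.histogram(vals, bins=edges)
        length = group.key[2]
        for left, c in zip(edges[:-1], hist):
            if c:
                rows.append((length, float(left), int(c)))
    out = pd.DataFrame(rows, columns=["cdr3_length", "identity_bin", "n_clonotypes"])
    return out.groupby(["cdr3_length", "identity_bin"], as_index=False)["n_clonotypes"].sum()


@dataclass
class LineageNetwork:
    """Thresholded similarity graph over distinct CDR3 nt clonotypes.

    Nodes are (V, J, CDR3 nt) triples with ``count`` attributes; edges
    join same-group pairs at >= ``threshold_pct`` identity; ``lineages``
    are the connected components with >= ``min_nodes`` members.
    """

    graph: nx.Graph
    lineages: list[frozenset[NodeKey]]
    threshold_pct: float
    min_nodes: int

    @property
    def n_clonotypes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def lineage_nodes(self) -> set[NodeKey]:
        return set().union(*self.lineages) if self.lineages else set()


def build_lineages(
    df: pd.DataFrame, threshold_pct: float = 95.0, min_nodes: int = 2
) -> LineageNetwork:
    """Build the clonal-lineage network of one sample x isotype subset.

    Every distinct (V, J, CDR3 nt) clonotype becomes a node. Edges join
    pairs in the same (V, J, length) group whose identity is >= the
    threshold (inclusive, with a 1e-9 slack against float rounding);
    lineages are single-linkage connected components of size >=
    ``min_nodes``.
    """
    graph = nx.Graph()
    for group in group_by_vjl(df):
        v, j, _ = group.key
        nodes = [(v, j, s) for s in group.seqs]
        for node, count in zip(nodes, group.counts):
            graph.add_node(node, count=int(count))
        if len(group) >= 2:
            ident = _identity_matrix(group.seqs)
            ii, jj = np.nonzero(np.triu(ident >= threshold_pct - IDENTITY_TOL, k=1))
            graph.add_edges_from((nodes[a], nodes[b]) for a, b in zip(ii, jj))
    lineages = [
        frozenset(comp)
        for comp in nx.connected_components(graph)
        if len(comp) >= max(min_nodes, 2)
    ]
    lineages.sort(key=lambda c: (-len(c), min(c)))
    return LineageNetwork(
        graph=graph, lineages=lineages, threshold_pct=threshold_pct, min_nodes=min_nodes
    )


def mutated_ratio(net: LineageNetwork, total_clonotypes: int | None = None) -> float:
    """Percent of clonotypes that belong to a clonal lineage.

    ``total_clonotypes`` defaults to the number of distinct nt
    clonotypes in the network.
    """
    total = net.n_clonotypes if total_clonotypes is None else total_clonotypes
    if total < 1:
        raise ValueError("total clonotype count must be >= 1")
    in_lineage = sum(len(c) for c in net.lineages)
    return 100.0 * in_lineage / total


@dataclass
class DegreeStats:
    """Degree distribution over lineage nodes and the sample's max degree.

    ``ratios`` is indexed 1..cap; the last entry pools degrees >= cap.
    Ratios sum to 1 when any lineage exists, and are empty otherwise.
    """

    ratios: pd.Series
    max_degree: int


def degree_stats(net: LineageNetwork, cap: int = 8) -> DegreeStats:
    """Node-degree distribution of the lineage network.

    The distribution covers lineage members only (isolated clonotypes
    have degree 0 and are excluded); the maximal degree is taken over
    all nodes.
    """
    degrees = dict(net.graph.degree())
    max_degree = max(degrees.values(), default=0)
    lineage_degrees = [degrees[n] for n in net.lineage_nodes]
    if not lineage_degrees:
        return DegreeStats(ratios=pd.Series(dtype=float), max_degree=int(max_degree))
    capped = np.minimum(lineage_degrees, cap)
    counts = pd.Series(capped).value_counts().reindex(range(1, cap + 1), fill_value=0)
    return DegreeStats(ratios=counts / counts.sum(), max_degree=int(max_degree))
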