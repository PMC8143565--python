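"""Graph data model, file I/O, bundled fixtures, and node-importance ranking.

The algorithms in this package operate on simple, undirected, unweighted
graphs.  :class:`Network` stores such a graph with arbitrary (hashable) node
identifiers mapped to dense 0-based internal indices; all public outputs are
reported in terms of the original identifiers.

Node importance is degree centrality ``DC(i) = k_i / (n - 1)``: the degree
normalized by the maximum degree a node could have in a simple graph.  The
induced processing order (descending centrality, ties broken by ascending
node id) is the deterministic backbone of LPA-MNI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger("lpamni")

NodeId = Hashable
#: A partition assigns every node of a network exactly one community label.
Partition = Mapping[NodeId, Hashable]

FIXTURE_NAMES = ("karate", "two_cliques", "two_triangles")

#: Members of community 1 in the canonical two-faction split of the Zachary
#: karate club (1-based ids); community 2 is the complement of the 34 nodes.
KARATE_COMMUNITY_1 = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 11, 12, 13, 14, 17, 18, 20, 22}
)


class Network:
    """A simple undirected unweighted graph.

    Parameters
    ----------
    edges:
        Iterable of ``(u, v)`` pairs.  Self-loops and duplicate edges are
        dropped with a logged warning.
    nodes:
        Optional iterable of node ids to include (so isolated nodes survive).

    Node order is canonical: sorted when all ids are mutually comparable,
    first-seen order otherwise.  The canonical order defines the internal
    index of each node and the ascending-id tie rule used throughout.
    """

    __slots__ = ("_nodes", "_index", "_adj", "_degrees", "_m")

    def __init__(
        self,
        edges: Iterable[tuple[NodeId, NodeId]],
        nodes: Iterable[NodeId] = (),
    ) -> None:
        seen: dict[NodeId, None] = {}
        edge_list: list[tuple[NodeId, NodeId]] = []
        n_self = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                seen.setdefault(u, None)
                continue
            seen.setdefault(u, None)
            seen.setdefault(v, None)
            edge_list.append((u, v))
        for u in nodes:
            seen.setdefault(u, None)
        if not seen:
            raise ValueError("a Network needs at least one node")
        ids = list(seen)
        try:
            ids = sorted(ids)
        except TypeError:
            pass  # mixed-type ids keep first-seen order
        self._nodes: tuple[NodeId, ...] = tuple(ids)
        self._index: dict[NodeId, int] = {u: i for i, u in enumerate(ids)}
        adj: list[set[int]] = [set() for _ in ids]
        n_dup = 0
        m = 0
        for u, v in edge_list:
            iu, iv = self._index[u], self._index[v]
            if iv in adj[iu]:
                n_dup += 1
                continue
            adj[iu].add(iv)
            adj[iv].add(iu)
            m += 1
        if n_self:
            logger.warning("dropped %d self-loop(s)", n_self)
        if n_dup:
            logger.warning("dropped %d duplicate edge(s)", n_dup)
        self._adj = adj
        self._degrees = tuple(len(a) for a in adj)
        self._m = m

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        """Number of nodes ``|V|``."""
        return len(self._nodes)

    @property
    def m(self) -> int:
        """Number of edges ``|E|``."""
        return self._m

    @property
    def node_ids(self) -> tuple[NodeId, ...]:
        """Node identifiers in canonical order."""
        return self._nodes

    @property
    def adj(self) -> Sequence[set[int]]:
        """Adjacency as sets of internal indices, aligned with canonical order."""
        return self._adj

    @property
    def degrees(self) -> tuple[int, ...]:
        """Degree of each node, aligned with canonical order."""
        return self._degrees

    def index_of(self, node: NodeId) -> int:
        return self._index[node]

    def degree(self, node: NodeId) -> int:
        return self._degrees[self._index[node]]

    def neighbors(self, node: NodeId) -> tuple[NodeId, ...]:
        return tuple(self._nodes[j] for j in self._adj[self._index[node]])

    def edges(self) -> list[tuple[NodeId, NodeId]]:
        """Each undirected edge once, as (smaller-index, larger-index) ids."""
        return [
            (self._nodes[i], self._nodes[j])
            for i in range(self.n)
            for j in self._adj[i]
            if i < j
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self.edges())
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Network(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class ImportanceRanking:
    """Degree-centrality scores and the induced deterministic node order."""

    scores: dict[NodeId, float]
    order: tuple[NodeId, ...]
    #: same order expressed as internal indices, for the algorithms
    order_index: tuple[int, ...] = field(repr=False, default=())


def degree_centrality(net: Network) -> ImportanceRanking:
    """Rank nodes by normalized degree centrality ``DC(i) = k_i/(n-1)``.

    Isolated nodes score 0; a single-node network scores 0 by convention.
    Ties are broken by ascending node id (canonical order), so the ranking
    is a pure function of the network.
    """
    n = net.n
    denom = n - 1 if n > 1 else 1
    scores = {u: net.degrees[i] / denom for i, u in enumerate(net.node_ids)}
    order_index = tuple(
        sorted(range(n), key=lambda i: (-net.degrees[i], i))
    )
    order = tuple(net.node_ids[i] for i in order_index)
    return ImportanceRanking(scores=scores, order=order, order_index=order_index)


# -- file I/O --------------------------------------------------------------

def read_edge_list(path, strict: bool = False) -> Network:
    """Read a whitespace-separated edge list (``#`` comments allowed).

    Self-loops and duplicate edges are dropped with a warning; with
    ``strict=True`` a self-loop is an error instead.
    """
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two node tokens, got {line!r}"
                )
            u, v = tokens[0], tokens[1]
            if u == v:
                if strict:
                    raise ValueError(f"{path}: line {lineno}: self-loop {u!r}")
                nodes.append(u)
                continue
            edges.append((u, v))
    if not edges and not nodes:
        raise ValueError(f"{path}: no edges found")
    try:  # numeric ids sort numerically, not lexicographically
        edges = [(int(u), int(v)) for u, v in edges]
        nodes = [int(u) for u in nodes]
    except ValueError:
        pass
    return Network(edges, nodes=nodes)


def write_edge_list(net: Network, path) -> None:
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{u} {v}\n")


def read_gml(path) -> Network:
    """Read a graph from GML via networkx; ``directed`` is ignored with a warning."""
    g = nx.read_gml(path, label="id")
    if g.is_directed():
        warnings.warn(f"{path}: directed flag ignored; treating edges as undirected")
        g = g.to_undirected()
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty graph")
    return Network(g.edges(), nodes=g.nodes())


def read_membership(path) -> dict[NodeId, str]:
    """Read a ``node_id<TAB>community_label`` TSV into a partition dict."""
    part: dict[NodeId, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected node<TAB>label")
            part[fields[0]] = fields[1]
    if not part:
        raise ValueError(f"{path}: no membership rows")
    return part


def write_membership(part: Partition, path) -> None:
    with open(path, "w") as fh:
        for node in part:
            fh.write(f"{node}\t{part[node]}\n")


# -- bundled fixtures ------------------------------------------------------

def _karate() -> tuple[Network, dict[NodeId, int]]:
    ref = resources.files("lpamni.data").joinpath("karate.edgelist")
    with resources.as_file(ref) as p:
        net = read_edge_list(p)
    # edge-list tokens are strings "1".."34"
    truth = {
        u: 1 if int(u) in KARATE_COMMUNITY_1 else 2 for u in net.node_ids
    }
    return net, truth


def _two_cliques() -> tuple[Network, dict[NodeId, int]]:
    # two 4-cliques joined by the single bridge 4-5
    from itertools import combinations

    edges = list(combinations(range(1, 5), 2))
    edges += list(combinations(range(5, 9), 2))
    edges.append((4, 5))
    net = Network(edges)
    truth = {u: 1 if u <= 4 else 2 for u in net.node_ids}
    return net, truth


def _two_triangles() -> tuple[Network, dict[NodeId, int]]:
    edges = [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)]
    net = Network(edges)
    truth = {u: 1 if u <= 3 else 2 for u in net.node_ids}
    return net, truth


def load_fixture(name: str) -> tuple[Network, dict[NodeId, int]]:
    """Load a bundled test network and its ground-truth partition.

    Available fixtures: ``karate`` (Zachary karate club, 34 nodes / 78
    edges, canonical two-faction ground truth), ``two_cliques`` (two
    4-cliques joined by one bridge edge) and ``two_triangles`` (two
    disjoint triangles, ground truth = connected components).
    """
    loaders = {
        "karate": _karate,
        "two_cliques": _two_cliques,
        "two_triangles": _two_triangles,
    }
    try:
        return loaders[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
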