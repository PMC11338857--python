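"""Hydrogen-suppressed molecular graphs and their degree-based summaries.

A molecular graph here is the simple undirected graph of heavy atoms:
hydrogens are omitted, bond order is ignored (a double bond contributes a
single edge), and degrees count distinct heavy-atom neighbours.  This is the
convention under which the worked thalidomide example reproduces (19 vertices,
21 edges, carbonyl oxygens of degree 1).

Two summaries drive every index downstream:

* the *degree spectrum* — how many vertices have each degree;
* the *edge partition* — how many edges join a vertex of degree ``d_s`` to a
  vertex of degree ``d_t``, keyed by the unordered pair ``(min, max)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import networkx as nx

__all__ = [
    "GraphValidationError",
    "MolecularGraph",
    "from_edge_list",
    "degree_spectrum",
    "edge_partition",
    "relabel",
]

DegreePair = Tuple[int, int]


class GraphValidationError(ValueError):
    """Raised when an input does not describe a valid molecular graph."""


@dataclass(frozen=True)
class MolecularGraph:
    """A validated simple, connected graph of heavy atoms.

    Vertex labels are opaque strings; chemistry (elements, bond orders) is
    deliberately not represented.
    """

    _graph: nx.Graph = field(repr=False)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def vertex_labels(self) -> tuple:
        return tuple(self._graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._graph.edges)

    @property
    def n_vertices(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def degree(self, v) -> int:
        return self._graph.degree[v]


def _validate(g: nx.Graph, *, allow_disconnected: bool = False) -> nx.Graph:
    if g.number_of_nodes() == 0:
        raise GraphValidationError("graph has no vertices")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise GraphValidationError(f"self-loop at vertex {loops[0][0]!r}")
    if min(d for _, d in g.degree) < 1:
        isolated = [v for v, d in g.degree if d == 0]
        raise GraphValidationError(f"isolated vertex {isolated[0]!r}")
    if not allow_disconnected and not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len)
        raise GraphValidationError(
            f"graph is disconnected; smallest component: {sorted(map(str, comps[0]))}"
        )
    return g


def from_graph(g: nx.Graph, *, allow_disconnected: bool = False) -> MolecularGraph:
    """Wrap an existing networkx graph after validation."""
    return MolecularGraph(_validate(nx.Graph(g), allow_disconnected=allow_disconnected))


def from_edge_list(text: str, *, allow_disconnected: bool = False) -> MolecularGraph:
    """Parse an edge-list document into a validated :class:`MolecularGraph`.

    One edge per line: two whitespace-separated vertex labels.  Blank lines
    and ``#`` comments are allowed.  Self-loops, duplicate edges and (by
    default) disconnected graphs are rejected with the offending line named.
    """
    g = nx.Graph()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphValidationError(
                f"line {lineno}: expected two vertex labels, got {raw.strip()!r}"
            )
        u, v = parts
        if u == v:
            raise GraphValidationError(f"line {lineno}: self-loop {u!r}-{v!r}")
        if g.has_edge(u, v):
            raise GraphValidationError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
        g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise GraphValidationError("edge list is empty")
    return from_graph(g, allow_disconnected=allow_disconnected)


def to_edge_list(g: MolecularGraph) -> str:
    """Serialise a graph in the edge-list format accepted by :func:`from_edge_list`."""
    return "\n".join(f"{u} {v}" for u, v in g.graph.edges) + "\n"


def degree_spectrum(g: MolecularGraph) -> Dict[int, int]:
    """Map each degree value to the number of vertices having it.

    Satisfies the handshake lemma: ``sum(d * count) == 2 * |E|``.
    """
    return dict(Counter(d for _, d in g.graph.degree))


def edge_partition(g: MolecularGraph) -> Dict[DegreePair, int]:
    """Partition edges by the unordered degree pair of their endpoints.

    All six indices are symmetric in ``(d_s, d_t)``, so classes are stored as
    ``(min, max)``.  Frequencies sum to ``|E|``.
    """
    deg = dict(g.graph.degree)
    part: Counter = Counter()
    for u, v in g.graph.edges:
        ds, dt = sorted((deg[u], deg[v]))
        part[(ds, dt)] += 1
    return dict(part)


def relabel(g: MolecularGraph, permutation: Mapping) -> MolecularGraph:
    """Apply a bijective vertex relabelling; all indices are invariant under it."""
    labels = set(g.vertex_labels)
    if set(permutation.keys()) != labels:
        raise GraphValidationError("permutation domain does not match vertex set")
    if len(set(permutation.values())) != len(labels):
        raise GraphValidationError("permutation is not a bijection")
    return MolecularGraph(nx.relabel_nodes(g.graph, dict(permutation), copy=True))


def validate_partition(part: Mapping[DegreePair, int]) -> None:
    """Sanity-check an edge partition supplied directly (e.g. from a table)."""
    if not part:
        raise GraphValidationError("empty edge partition")
    for (ds, dt), f in part.items():
        if ds < 1 or dt < ds:
            raise GraphValidationError(f"invalid degree class {(ds, dt)}")
        if f < 1:
            raise GraphValidationError(f"non-positive frequency for class {(ds, dt)}")
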