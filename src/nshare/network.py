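"""In-memory containers: interaction networks, permitted-interaction relations, traits.

Conventions
-----------
* Node identifiers are opaque strings; no numeric coercion ever happens.
* Directed (unimode) edges are stored ``(source, target)`` meaning *source is a
  resource/partner of target* — i.e. resource→consumer orientation; the source
  is eaten by the target.  All file readers document this and offer a flip flag.
* Partner *direction* for unimode networks:

  - ``"out"``  — a node's partners are its resources (prey): the sources of the
    edges pointing into it.  This is the food-web default (shared prey).
  - ``"in"``   — a node's partners are its consumers: the targets of its
    outgoing edges (shared predators).
  - ``"undirected"`` — the union of both.

* Bipartite networks are undirected; edges always join the two sides (guilds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ModeError, ParameterError, UnknownNodeError

DIRECTIONS = ("out", "in", "undirected")


def _as_str_tuple(items: Iterable) -> tuple[str, ...]:
    return tuple(str(x) for x in items)


class Network:
    """A presence/absence interaction network (unimode directed or bipartite).

    Parameters
    ----------
    nodes
        Ordered collection of node identifiers (strings).  Order is preserved
        and defines matrix indexing; it does not affect any statistic.
    edges
        Iterable of ``(source, target)`` pairs.  For directed networks the pair
        is ordered resource→consumer.  For undirected networks pairs are
        normalized internally (lexicographically), so ``("b","a")`` and
        ``("a","b")`` denote the same edge.
    directed
        Directed unimode network if True.  Bipartite networks must be
        undirected.
    bipartite_sides
        Optional pair of disjoint node collections covering all nodes (the two
        guilds, e.g. hosts and parasites).  When present every edge must join
        the two sides.
    """

    __slots__ = ("nodes", "edges", "directed", "bipartite_sides", "_index", "_adj")

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        directed: bool = True,
        bipartite_sides: tuple[Iterable[str], Iterable[str]] | None = None,
        validate: bool = True,
    ):
        self.nodes = _as_str_tuple(nodes)
        self._index = {v: k for k, v in enumerate(self.nodes)}
        if bipartite_sides is not None:
            if directed:
                raise ModeError("bipartite networks are undirected")
            sides = (_as_str_tuple(bipartite_sides[0]), _as_str_tuple(bipartite_sides[1]))
        else:
            sides = None
        self.bipartite_sides = sides
        self.directed = bool(directed)
        norm = []
        for u, v in edges:
            u, v = str(u), str(v)
            if not self.directed and v < u:
                u, v = v, u
            norm.append((u, v))
        self.edges = frozenset(norm)
        self._adj = None
        if validate:
            self._validate()

    # -- validation ----------------------------------------------------------
    def _validate(self) -> None:
        if len(self._index) != len(self.nodes):
            raise ParameterError("duplicate node identifiers")
        for u, v in self.edges:
            if u not in self._index or v not in self._index:
                raise UnknownNodeError(f"edge endpoint not a declared node: ({u!r}, {v!r})")
        if self.bipartite_sides is not None:
            s0, s1 = map(set, self.bipartite_sides)
            if s0 & s1:
                raise ParameterError("bipartite sides are not disjoint")
            if s0 | s1 != set(self.nodes):
                raise ParameterError("bipartite sides do not cover the node set")
            for u, v in self.edges:
                if (u in s0) == (v in s0):
                    raise ParameterError(f"edge within one bipartite side: ({u!r}, {v!r})")

    # -- basic queries -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def is_bipartite(self) -> bool:
        return self.bipartite_sides is not None

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise UnknownNodeError(node) from None

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __eq__(self, other) -> bool:
        """Semantic equality: node order is an indexing detail, not content."""
        if not isinstance(other, Network):
            return NotImplemented
        if self.bipartite_sides is None:
            sides_eq = other.bipartite_sides is None
        else:
            sides_eq = other.bipartite_sides is not None and tuple(
                frozenset(s) for s in self.bipartite_sides
            ) == tuple(frozenset(s) for s in other.bipartite_sides)
        return (
            frozenset(self.nodes) == frozenset(other.nodes)
            and self.edges == other.edges
            and self.directed == other.directed
            and sides_eq
        )

    def __hash__(self):
        return hash((frozenset(self.nodes), self.edges, self.directed))

    def __repr__(self) -> str:
        kind = "bipartite" if self.is_bipartite else ("directed" if self.directed else "undirected")
        return f"<Network {kind}: {self.n_nodes} nodes, {len(self.edges)} edges>"

    # -- adjacency / partner masks -------------------------------------------
    def adjacency(self) -> np.ndarray:
        """Boolean matrix A with ``A[u, v]`` True iff edge (u, v) exists.

        Undirected networks yield a symmetric matrix.
        """
        if self._adj is None:
            n = self.n_nodes
            A = np.zeros((n, n), dtype=bool)
            idx = self._index
            for u, v in self.edges:
                A[idx[u], idx[v]] = True
                if not self.directed:
                    A[idx[v], idx[u]] = True
            self._adj = A
        return self._adj

    def partner_matrix(self, direction: str = "out") -> np.ndarray:
        """Matrix whose column ``v`` is the realized-partner mask of node ``v``.

        ``direction="out"`` gives resource (prey) sets for directed networks;
        ``"in"`` gives consumer sets; ``"undirected"`` their union.  Undirected
        networks only accept ``"undirected"``.
        """
        if direction not in DIRECTIONS:
            raise ParameterError(f"unknown direction {direction!r}")
        A = self.adjacency()
        if not self.directed:
            if direction != "undirected":
                raise ModeError("directed partner lookup on an undirected network")
            return A
        if direction == "out":
            return A
        if direction == "in":
            return A.T
        return A | A.T

    def partners(self, node: str, direction: str = "out") -> frozenset[str]:
        """Realized partner set of one node under the given direction."""
        mask = self.partner_matrix(direction)[:, self.index(node)]
        return frozenset(self.nodes[k] for k in np.flatnonzero(mask))

    def side_of(self, node: str) -> int:
        """0 or 1: which bipartite side a node belongs to."""
        if not self.is_bipartite:
            raise ModeError("side_of on a unimode network")
        self.index(node)
        return 0 if node in set(self.bipartite_sides[0]) else 1

    # -- interop -------------------------------------------------------------
    def to_networkx(self):
        """Export as a :mod:`networkx` graph (DiGraph when directed)."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_networkx(cls, g, bipartite_sides=None) -> "Network":
        return cls(
            nodes=list(g.nodes()),
            edges=list(g.edges()),
            directed=g.is_directed(),
            bipartite_sides=bipartite_sides,
        )


class PermittedInteractions:
    """Binary relation declaring which ordered links are ecologically possible.

    ``matrix[u, v]`` is True when node ``u`` is a *permitted* partner of node
    ``v`` in the resource role — i.e. the (potential) link u→v is allowed,
    whether or not it is realized.  Indexing follows the attached network's
    node order.  For bipartite relations the matrix is symmetric (the same
    indicator serves host-side and parasite-side computations) and all
    within-side entries are False.

    When ``loops_allowed`` is False the diagonal is identically False, which
    automatically removes the two focal nodes from every pair's shareable set
    (the n−2 correction in the fully permissive case).
    """

    __slots__ = ("nodes", "matrix", "loops_allowed", "_index")

    def __init__(self, nodes: Iterable[str], matrix: np.ndarray, loops_allowed: bool = False):
        self.nodes = _as_str_tuple(nodes)
        self._index = {v: k for k, v in enumerate(self.nodes)}
        m = np.asarray(matrix, dtype=bool).copy()
        if m.shape != (len(self.nodes), len(self.nodes)):
            raise ParameterError(
                f"permitted matrix shape {m.shape} does not match {len(self.nodes)} nodes"
            )
        self.loops_allowed = bool(loops_allowed)
        if not self.loops_allowed:
            np.fill_diagonal(m, False)
        m.flags.writeable = False
        self.matrix = m

    # -- constructors ---------------------------------------------------------
    @classmethod
    def fully_permissive(cls, net: Network, loops_allowed: bool = False) -> "PermittedInteractions":
        """Every ecologically conceivable link allowed.

        Unimode: all ordered pairs (minus loops unless allowed).  Bipartite:
        all cross-side pairs — the naive ``n`` = size of the opposite guild.
        """
        n = net.n_nodes
        if net.is_bipartite:
            m = np.zeros((n, n), dtype=bool)
            s0 = np.array([net.side_of(v) == 0 for v in net.nodes])
            m[np.ix_(s0, ~s0)] = True
            m[np.ix_(~s0, s0)] = True
            return cls(net.nodes, m, loops_allowed=False)
        m = np.ones((n, n), dtype=bool)
        return cls(net.nodes, m, loops_allowed=loops_allowed)

    @classmethod
    def none_permitted(cls, net: Network) -> "PermittedInteractions":
        return cls(net.nodes, np.zeros((net.n_nodes, net.n_nodes), dtype=bool))

    # -- queries --------------------------------------------------------------
    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise UnknownNodeError(node) from None

    def allows(self, partner: str, actor: str) -> bool:
        """True when *partner* may act as a resource/partner of *actor*."""
        return bool(self.matrix[self.index(partner), self.index(actor)])

    def partner_matrix(self, direction: str = "out") -> np.ndarray:
        """Column ``v`` = mask of permitted partners of node ``v`` under direction."""
        if direction not in DIRECTIONS:
            raise ParameterError(f"unknown direction {direction!r}")
        if direction == "out":
            return self.matrix
        if direction == "in":
            return self.matrix.T
        return self.matrix | self.matrix.T

    def permitted_partners(self, node: str, direction: str = "out") -> frozenset[str]:
        mask = self.partner_matrix(direction)[:, self.index(node)]
        return frozenset(self.nodes[k] for k in np.flatnonzero(mask))

    def attached_to(self, net: Network) -> bool:
        return self.nodes == net.nodes

    def restrict(self, nodes: Sequence[str]) -> "PermittedInteractions":
        """Sub-relation over a subset of nodes (order as given)."""
        idx = np.array([self.index(v) for v in nodes])
        return PermittedInteractions(
            nodes, self.matrix[np.ix_(idx, idx)], loops_allowed=self.loops_allowed
        )


@dataclass(frozen=True)
class TraitTable:
    """Mapping node → set of trait/task tokens (e.g. Avida logical operations).

    Empty token sets are legal: a host that performs no tasks simply cannot be
    parasitized under the task-matching rule.
    """

    traits: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self,
            "traits",
            {str(k): frozenset(str(t) for t in v) for k, v in dict(self.traits).items()},
        )

    def __getitem__(self, node: str) -> frozenset[str]:
        try:
            return self.traits[node]
        except KeyError:
            raise UnknownNodeError(node) from None

    def __contains__(self, node: str) -> bool:
        return node in self.traits

    def missing_from(self, net: Network) -> list[str]:
        """Node ids of *net* with no trait entry (sorted)."""
        return sorted(v for v in net.nodes if v not in self.traits)

    def validate_against(self, net: Network) -> None:
        unknown = sorted(v for v in self.traits if v not in net)
        if unknown:
            raise UnknownNodeError(f"trait table keys not in network: {unknown}")
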