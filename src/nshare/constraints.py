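"""Permitted-interaction relations from ecological rules.

Three generators are provided:

* **Trophic rule** (food webs): a link is permitted only from a resource to a
  consumer at a strictly higher trophic level, with trophic level defined as
  the minimum path distance from any basal resource (a species with no prey).
* **Task matching** (host–parasite webs): a parasite can use a host only if
  the two share at least one trait/task token (e.g. an Avida logical
  operation).
* **User-supplied matrix**: any labeled 0/1 table.

`reduction_report` quantifies how much a rule shrinks each node's set of
potential partners relative to the unconstrained set.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ModeError, ParameterError, UnknownNodeError
from .network import Network, PermittedInteractions, TraitTable

#: Trophic level assigned to nodes with no directed path from any basal node
#: (e.g. members of an isolated cycle).  Such nodes take part in no permitted
#: interaction under the trophic rule.
UNREACHABLE = None


@dataclass(frozen=True)
class TrophicLevels:
    """Minimum-path trophic levels: basal = 0, consumers = shortest distance."""

    level: Mapping[str, int | None]
    basal: frozenset[str]

    def __getitem__(self, node: str) -> int | None:
        try:
            return self.level[node]
        except KeyError:
            raise UnknownNodeError(node) from None

    @property
    def n_unreachable(self) -> int:
        return sum(1 for v in self.level.values() if v is UNREACHABLE)

    def to_dict(self) -> dict:
        return {k: self.level[k] for k in self.level}


def trophic_levels(net: Network) -> TrophicLevels:
    """Minimum path distance of each species to a basal resource.

    Basal species have no prey (in-degree zero under the resource→consumer
    edge orientation, self-loops ignored) and get level 0.  Other levels come
    from a multi-source breadth-first search from all basal nodes along
    realized edges; nodes unreachable from every basal node get
    :data:`UNREACHABLE`.  A web with no basal node at all yields all-
    unreachable levels plus a warning (not an exception).
    """
    if net.is_bipartite or not net.directed:
        raise ModeError("trophic levels require a directed unimode network")
    nodes = net.nodes
    has_prey = {v: False for v in nodes}
    consumers: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in net.edges:
        if u == v:  # cannibalism never makes a species non-basal
            continue
        has_prey[v] = True
        consumers[u].append(v)
    basal = frozenset(v for v in nodes if not has_prey[v])
    level: dict[str, int | None] = {v: UNREACHABLE for v in nodes}
    if not basal:
        warnings.warn("network has no basal node; all trophic levels undefined", stacklevel=2)
        return TrophicLevels(level=level, basal=basal)
    queue = deque()
    for v in basal:
        level[v] = 0
        queue.append(v)
    while queue:
        u = queue.popleft()
        d1 = level[u] + 1
        for w in consumers[u]:
            if level[w] is UNREACHABLE:
                level[w] = d1
                queue.append(w)
    return TrophicLevels(level=level, basal=basal)


def trophic_permitted(net: Network, tl: TrophicLevels | None = None) -> PermittedInteractions:
    """Permit only links from a resource to a consumer at a higher trophic level.

    Unreachable nodes end up with no permitted interaction in either role.
    The resulting relation is antisymmetric, loop-free and acyclic by
    construction (levels strictly increase along permitted links).
    """
    if tl is None:
        tl = trophic_levels(net)
    lv = np.array(
        [-1 if tl[v] is UNREACHABLE else tl[v] for v in net.nodes], dtype=np.int64
    )
    defined = lv >= 0
    # matrix[r, c]: r permitted as resource of c  <=>  level(r) < level(c)
    m = defined[:, None] & defined[None, :] & (lv[:, None] < lv[None, :])
    return PermittedInteractions(net.nodes, m, loops_allowed=False)


def task_match_permitted(
    net: Network, traits: TraitTable, actor_side: str = "cols"
) -> PermittedInteractions:
    """Permit a host–parasite link iff the two nodes share ≥1 trait token.

    The indicator depends only on the unordered pair of trait sets, so the
    same symmetric relation serves overlap computations on either guild;
    *actor_side* ("rows"/"cols") is accepted for interface symmetry and does
    not change the relation.
    """
    if not net.is_bipartite:
        raise ModeError("task matching requires a bipartite network")
    if actor_side not in ("rows", "cols"):
        raise ParameterError(f"actor_side must be 'rows' or 'cols', got {actor_side!r}")
    missing = traits.missing_from(net)
    if missing:
        raise UnknownNodeError(f"nodes missing from trait table: {missing}")
    n = net.n_nodes
    side0 = np.array([net.side_of(v) == 0 for v in net.nodes])
    cross = side0[:, None] != side0[None, :]
    share = np.zeros((n, n), dtype=bool)
    tsets = [traits[v] for v in net.nodes]
    for a in range(n):
        if not tsets[a]:
            continue
        for b in range(a + 1, n):
            if cross[a, b] and not tsets[a].isdisjoint(tsets[b]):
                share[a, b] = share[b, a] = True
    return PermittedInteractions(net.nodes, share, loops_allowed=False)


def permitted_from_matrix(net: Network, matrix: pd.DataFrame) -> PermittedInteractions:
    """Wrap a labeled 0/1 table as a permitted relation, with validation.

    Unimode: a square table labeled by all nodes on both axes; cell (r, c)=1
    permits r as a resource of c; ``loops_allowed`` is inferred from the
    diagonal.  Bipartite: a rectangular table, rows = partner guild, columns =
    actor guild (either orientation of the two sides); expanded to the
    symmetric square relation.
    """
    vals = matrix.to_numpy()
    uniq = set(np.unique(vals).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, True, False}:
        raise FormatError(f"permitted matrix entries must be 0/1, found {sorted(uniq)!r}")
    vals = vals.astype(bool)
    rows = [str(r) for r in matrix.index]
    cols = [str(c) for c in matrix.columns]
    if net.is_bipartite:
        s0, s1 = (sorted(s) for s in net.bipartite_sides)
        if sorted(rows) == s0 and sorted(cols) == s1:
            pass
        elif sorted(rows) == s1 and sorted(cols) == s0:
            vals, rows, cols = vals.T, cols, rows
        else:
            raise UnknownNodeError(
                "matrix labels do not match the two bipartite sides of the network"
            )
        m = np.zeros((net.n_nodes, net.n_nodes), dtype=bool)
        ridx = [net.index(r) for r in rows]
        cidx = [net.index(c) for c in cols]
        for a, ia in enumerate(ridx):
            for b, ib in enumerate(cidx):
                if vals[a, b]:
                    m[ia, ib] = m[ib, ia] = True
        return PermittedInteractions(net.nodes, m, loops_allowed=False)
    if sorted(rows) != sorted(net.nodes) or sorted(cols) != sorted(net.nodes):
        raise UnknownNodeError("matrix labels do not match the network's node set")
    if len(rows) != len(cols):
        raise FormatError("unimode permitted matrix must be square")
    m = np.zeros((net.n_nodes, net.n_nodes), dtype=bool)
    for a, r in enumerate(rows):
        ia = net.index(r)
        for b, c in enumerate(cols):
            m[ia, net.index(c)] = vals[a, b]
    loops = bool(m.diagonal().any())
    return PermittedInteractions(net.nodes, m, loops_allowed=loops)


@dataclass(frozen=True)
class ReductionReport:
    """Per-node ratios |constrained potential partners| / |unconstrained|."""

    per_node_ratio: Mapping[str, float]
    mean_ratio: float

    def to_dict(self) -> dict:
        return {"mean_ratio": self.mean_ratio, "per_node_ratio": dict(self.per_node_ratio)}


def reduction_report(
    net: Network, permitted: PermittedInteractions, direction: str = "out"
) -> ReductionReport:
    """How much a constraint shrinks each node's potential-partner set.

    The unconstrained set is all other nodes (unimode, loops forbidden; all
    nodes including self when the relation allows loops) or the full opposite
    guild (bipartite).  Ratios are reduced/complete, in [0, 1].
    """
    if not permitted.attached_to(net):
        raise ParameterError("permitted relation is not attached to this network")
    counts = permitted.partner_matrix(direction).sum(axis=0)
    ratios: dict[str, float] = {}
    for k, v in enumerate(net.nodes):
        if net.is_bipartite:
            denom = len(net.bipartite_sides[1 - net.side_of(v)])
        else:
            denom = net.n_nodes if permitted.loops_allowed else net.n_nodes - 1
        ratios[v] = float(counts[k] / denom) if denom else float("nan")
    vals = [r for r in ratios.values() if not np.isnan(r)]
    mean = float(np.mean(vals)) if vals else float("nan")
    return ReductionReport(per_node_ratio=ratios, mean_ratio=mean)


def validate_realized_against_permitted(
    net: Network, permitted: PermittedInteractions
) -> list[tuple[str, str]]:
    """Realized edges that violate the permitted relation (warn, never fail).

    Real food webs can contain same-level feeding that the trophic rule
    forbids; such links are simply dropped from each pair's hypergeometric
    support during overlap computation.
    """
    bad = sorted(
        (u, v)
        for u, v in net.edges
        if not permitted.matrix[net.index(u), net.index(v)]
        and not (not net.directed and permitted.matrix[net.index(v), net.index(u)])
    )
    if bad:
        warnings.warn(
            f"{len(bad)} realized edge(s) violate the permitted relation "
            "(they will be ignored within shareable sets)",
            stacklevel=2,
        )
    return bad
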