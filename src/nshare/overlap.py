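"""Standardized pairwise node overlap and its network mean.

For a pair of nodes (i, j), let A_ij be the *shareable set*: the partners both
nodes could possibly (permittedly) share, of size n.  With d_i, d_j the
realized partner counts of i and j *within* A_ij and O the number of shared
realized partners, the expected overlap under the hypergeometric sampling
distribution (each member of A_ij equally likely to be linked) is

    E = d_i * d_j / n,

bounded by s_min = max(0, d_i + d_j − n) and s_max = min(d_i, d_j).  The
standardized pairwise overlap maps {s_min, E, s_max} linearly onto
{−1, 0, +1}:

    value = (O − E) / (s_max − E)   if O ≥ E,
    value = (O − E) / (E − s_min)   if O < E.

+1 is complete overlap (nestedness at the pair level), −1 complete
segregation, 0 the random expectation.  The network statistic N̄ is the
arithmetic mean over all candidate pairs whose value is defined.

Degenerate pairs — n = 0, a zero realized degree, or a forced outcome
(s_min = s_max) — carry no information about overlap tendency and are
excluded from the mean by default (counted and reported); forced pairs can
instead be scored 0 via ``degenerate_policy="zero"``.

All branch decisions (O ≥ E, s_max > E) are taken in exact integer
arithmetic: O·n vs d_i·d_j, never in floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import ModeError, PairError, ParameterError, UnknownNodeError
from .network import Network, PermittedInteractions

SCOPES = ("rows", "cols", "both-guilds", "unimode-out", "unimode-in", "unimode-undirected")


@dataclass(frozen=True)
class PairOverlap:
    """Full decomposition of one pairwise overlap computation."""

    node_i: str
    node_j: str
    n: int
    d_i: int
    d_j: int
    observed: int
    expected: float
    s_min: int
    s_max: int
    value: float  # NaN when degenerate
    degenerate: bool
    reason: str | None = None  # "empty-shareable-set" | "zero-degree" | "forced"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)

    def to_dict(self) -> dict:
        d = {
            "node_i": self.node_i,
            "node_j": self.node_j,
            "n": self.n,
            "d_i": self.d_i,
            "d_j": self.d_j,
            "observed": self.observed,
            "expected": None if math.isnan(self.expected) else self.expected,
            "s_min": self.s_min,
            "s_max": self.s_max,
            "value": None if math.isnan(self.value) else self.value,
            "degenerate": self.degenerate,
            "reason": self.reason,
        }
        return d


@dataclass(frozen=True)
class OverlapSummary:
    """N̄ plus bookkeeping for one network/constraint/scope combination."""

    mean_overlap: float  # NaN when no includable pair
    pair_records: tuple[PairOverlap, ...]
    n_pairs_included: int
    n_pairs_excluded_degenerate: int
    n_pairs_excluded_zero_degree: int
    scope: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mean_overlap)

    @property
    def n_pairs_total(self) -> int:
        return (
            self.n_pairs_included
            + self.n_pairs_excluded_degenerate
            + self.n_pairs_excluded_zero_degree
        )

    def to_dict(self, per_pair: bool = False, constraint: str | None = None) -> dict:
        out = {
            "scope": self.scope,
            "constraint": constraint,
            "n_bar": None if math.isnan(self.mean_overlap) else self.mean_overlap,
            "n_bar_defined": self.defined,
            "pairs_included": self.n_pairs_included,
            "pairs_excluded_degenerate": self.n_pairs_excluded_degenerate,
            "pairs_excluded_zero_degree": self.n_pairs_excluded_zero_degree,
        }
        if per_pair:
            out["per_pair"] = [p.to_dict() for p in self.pair_records]
        return out


# ---------------------------------------------------------------------------
# pairwise computation
# ---------------------------------------------------------------------------

def _check_pair(net: Network, i: str, j: str) -> None:
    net.index(i)
    net.index(j)
    if i == j:
        raise PairError(
            f"cannot pair node {i!r} with itself; loops are handled by the permitted relation"
        )


def shareable_set(
    net: Network,
    permitted: PermittedInteractions,
    i: str,
    j: str,
    direction: str = "out",
) -> frozenset[str]:
    """A_ij: nodes permitted as partners of *both* i and j under `direction`.

    |A_ij| is the hypergeometric population size n for the pair.  With a fully
    permissive relation and loops forbidden, A_ij excludes i and j themselves,
    realizing the n−2 cannibalism correction for unimode webs.
    """
    _check_pair(net, i, j)
    if not permitted.attached_to(net):
        raise ParameterError("permitted relation is not attached to this network")
    if not net.directed and direction != "undirected":
        raise ModeError("direction=out/in on an undirected network")
    P = permitted.partner_matrix(direction)
    mask = P[:, net.index(i)] & P[:, net.index(j)]
    return frozenset(net.nodes[k] for k in np.flatnonzero(mask))


def _pair_from_masks(
    i: str,
    j: str,
    a_mask: np.ndarray,
    ri: np.ndarray,
    rj: np.ndarray,
) -> PairOverlap:
    """Assemble a PairOverlap from the shareable-set mask and realized masks."""
    n = int(a_mask.sum())
    di_mask = ri & a_mask
    dj_mask = rj & a_mask
    d_i = int(di_mask.sum())
    d_j = int(dj_mask.sum())
    obs = int((di_mask & dj_mask).sum())
    if n == 0:
        return PairOverlap(i, j, 0, 0, 0, 0, math.nan, 0, 0, math.nan, True, "empty-shareable-set")
    expected = d_i * d_j / n
    s_min = max(0, d_i + d_j - n)
    s_max = min(d_i, d_j)
    if d_i == 0 or d_j == 0:
        return PairOverlap(i, j, n, d_i, d_j, obs, expected, s_min, s_max,
                           math.nan, True, "zero-degree")
    if s_min == s_max:
        return PairOverlap(i, j, n, d_i, d_j, obs, expected, s_min, s_max,
                           math.nan, True, "forced")
    # exact integer arithmetic: O - E and the denominators share the factor 1/n
    num = obs * n - d_i * d_j
    if num >= 0:
        value = num / (s_max * n - d_i * d_j)
    else:
        value = num / (d_i * d_j - s_min * n)
    return PairOverlap(i, j, n, d_i, d_j, obs, expected, s_min, s_max, value, False, None)


def pair_overlap(
    net: Network,
    permitted: PermittedInteractions,
    i: str,
    j: str,
    direction: str = "out",
) -> PairOverlap:
    """Standardized overlap of one node pair within its shareable set.

    Realized partners falling outside A_ij are dropped from the pair's degrees
    (degrees and O live strictly on the hypergeometric support), which keeps
    s_min ≤ O ≤ s_max provable even when realized edges violate the permitted
    relation.
    """
    _check_pair(net, i, j)
    if not permitted.attached_to(net):
        raise ParameterError("permitted relation is not attached to this network")
    if not net.directed and direction != "undirected":
        raise ModeError("direction=out/in on an undirected network")
    P = permitted.partner_matrix(direction)
    R = net.partner_matrix(direction if net.directed else "undirected")
    ii, jj = net.index(i), net.index(j)
    a_mask = P[:, ii] & P[:, jj]
    return _pair_from_masks(i, j, a_mask, R[:, ii], R[:, jj])


# ---------------------------------------------------------------------------
# network mean
# ---------------------------------------------------------------------------

def _resolve_scope(net: Network, scope: str | None, direction: str) -> tuple[str, str, list[str]]:
    """Return (scope-tag, effective direction, nodes forming candidate pairs)."""
    if scope in (None, "auto"):
        scope = "both-guilds" if net.is_bipartite else f"unimode-{direction}"
    if scope.startswith("unimode-"):
        direction = scope.split("-", 1)[1]
    if scope in ("rows", "cols", "both-guilds"):
        if not net.is_bipartite:
            raise ModeError(f"scope {scope!r} requires a bipartite network")
        direction = "undirected"
    elif scope in ("unimode-out", "unimode-in", "unimode-undirected"):
        if net.is_bipartite:
            raise ModeError(f"scope {scope!r} requires a unimode network")
        if not net.directed and direction != "undirected":
            raise ModeError("direction=out/in on an undirected network")
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    if scope == "rows":
        nodes = sorted(net.bipartite_sides[0])
    elif scope == "cols":
        nodes = sorted(net.bipartite_sides[1])
    else:
        nodes = sorted(net.nodes)
    return scope, direction, nodes


def _candidate_pairs(net: Network, scope: str, nodes: list[str]):
    if scope == "both-guilds":
        s0 = sorted(net.bipartite_sides[0])
        s1 = sorted(net.bipartite_sides[1])
        yield from combinations(s0, 2)
        yield from combinations(s1, 2)
    else:
        yield from combinations(nodes, 2)


def mean_overlap(
    net: Network,
    permitted: PermittedInteractions | None = None,
    scope: str | None = None,
    direction: str = "out",
    degenerate_policy: str = "exclude",
    keep_pairs: bool = True,
) -> OverlapSummary:
    """N̄: mean standardized overlap over every candidate pair in scope.

    Parameters
    ----------
    permitted
        Permitted-interaction relation; None means fully permissive with
        loops forbidden (the naive specification of n).
    scope
        ``rows`` / ``cols`` / ``both-guilds`` for bipartite networks (pairs
        within one or both guilds, sharing partners on the opposite side);
        ``unimode-out`` / ``unimode-in`` / ``unimode-undirected`` for unimode
        webs; None picks ``both-guilds`` or ``unimode-<direction>``.
    degenerate_policy
        ``"exclude"`` (default) drops forced pairs from the mean;
        ``"zero"`` scores them 0.  Pairs with an empty shareable set or a
        zero realized degree are always excluded.
    keep_pairs
        Retain per-pair records on the summary (set False for large batches).
    """
    if degenerate_policy not in ("exclude", "zero"):
        raise ParameterError(f"unknown degenerate_policy {degenerate_policy!r}")
    if permitted is None:
        permitted = PermittedInteractions.fully_permissive(net)
    if not permitted.attached_to(net):
        raise ParameterError("permitted relation is not attached to this network")
    scope, direction, nodes = _resolve_scope(net, scope, direction)
    P = permitted.partner_matrix(direction)
    R = net.partner_matrix(direction if net.directed else "undirected")

    records: list[PairOverlap] = []
    values: list[float] = []
    n_deg = n_zero = 0
    for i, j in _candidate_pairs(net, scope, nodes):
        ii, jj = net.index(i), net.index(j)
        rec = _pair_from_masks(i, j, P[:, ii] & P[:, jj], R[:, ii], R[:, jj])
        if keep_pairs:
            records.append(rec)
        if rec.reason == "zero-degree":
            n_zero += 1
        elif rec.degenerate:
            if rec.reason == "forced" and degenerate_policy == "zero":
                values.append(0.0)
            else:
                n_deg += 1
        else:
            values.append(rec.value)
    if rec_count := len(values):
        mean = float(np.mean(values))
    else:
        mean = math.nan
    return OverlapSummary(
        mean_overlap=mean,
        pair_records=tuple(records),
        n_pairs_included=rec_count,
        n_pairs_excluded_degenerate=n_deg,
        n_pairs_excluded_zero_degree=n_zero,
        scope=scope,
    )


# ---------------------------------------------------------------------------
# simple network diagnostics
# ---------------------------------------------------------------------------

def connectance(net: Network, include_loops: bool = False) -> float:
    """Fraction of realized links over all possible ones.

    Bipartite: |E| / (|side0|·|side1|).  Unimode directed: |E| / (N(N−1)),
    loops excluded from numerator and denominator by default
    (``include_loops=True`` uses N² and counts realized loops).
    Returns NaN for an empty network.
    """
    if net.n_nodes == 0:
        return math.nan
    if net.is_bipartite:
        a, b = len(net.bipartite_sides[0]), len(net.bipartite_sides[1])
        if a * b == 0:
            return math.nan
        return len(net.edges) / (a * b)
    n = net.n_nodes
    if net.directed:
        if include_loops:
            return len(net.edges) / (n * n)
        if n < 2:
            return math.nan
        m = sum(1 for u, v in net.edges if u != v)
        return m / (n * (n - 1))
    if n < 2:
        return math.nan
    m = sum(1 for u, v in net.edges if u != v)
    return m / (n * (n - 1) / 2)


def mean_shared_partners(
    net: Network, scope: str | None = None, direction: str = "out"
) -> float:
    """Mean raw count of shared realized partners over all pairs in scope.

    No constraint, no standardization — the diagnostic quantity that, e.g.,
    is below one in very sparse pollination webs.  NaN with <2 nodes in scope.
    """
    scope, direction, nodes = _resolve_scope(net, scope, direction)
    R = net.partner_matrix(direction if net.directed else "undirected")
    counts = [
        int((R[:, net.index(i)] & R[:, net.index(j)]).sum())
        for i, j in _candidate_pairs(net, scope, nodes)
    ]
    if not counts:
        return math.nan
    return float(np.mean(counts))
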