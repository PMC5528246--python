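"""Synthetic networks with controlled structure.

These generators let every analysis the package supports be exercised without
external data: Bernoulli bipartite webs (the null benchmark for the overlap
statistic), perfectly nested and block-modular bipartite webs (the two
archetypal regimes, overlap and segregation), layered food webs with known
trophic levels, and task-based host–parasite worlds emulating digital
(Avida-style) co-evolution experiments, where realized infection links are a
subset of a task-matching permitted set.

All randomness flows from one `numpy.random.Generator` seeded per call; no
global state.  Identical configuration + seed give identical networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import GenerationError, ParameterError
from .network import Network, PermittedInteractions, TraitTable

_ROW, _COL = "R", "C"


def _names(prefix: str, count: int) -> list[str]:
    width = max(2, len(str(max(count - 1, 0))))
    return [f"{prefix}{k:0{width}d}" for k in range(count)]


def _bipartite_from_mask(rows: list[str], cols: list[str], mask: np.ndarray) -> Network:
    edges = [(rows[a], cols[b]) for a, b in zip(*np.nonzero(mask))]
    return Network(
        nodes=rows + cols,
        edges=edges,
        directed=False,
        bipartite_sides=(rows, cols),
    )


def gen_bipartite_bernoulli(rows: int, cols: int, connectance: float, seed: int) -> Network:
    """Each cell of the incidence matrix realized independently with p = connectance."""
    if rows <= 0 or cols <= 0:
        raise ParameterError("rows and cols must be positive")
    if not 0 < connectance <= 1:
        raise ParameterError("connectance must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((rows, cols)) < connectance
    return _bipartite_from_mask(_names(_ROW, rows), _names(_COL, cols), mask)


def _nested_mask(rows: int, cols: int, fill: float) -> np.ndarray:
    """Perfectly nested (Young-diagram) incidence at the target fill.

    Cell (i, j) is filled iff i/rows + j/cols < t, with t chosen by bisection
    so the realized fill is as close as possible to the target.  Row partner
    sets are then prefixes of columns, so each row's set contains the next
    row's: every pair of rows is a subset pair.
    """
    ii = np.arange(rows)[:, None] / rows
    jj = np.arange(cols)[None, :] / cols
    target = fill * rows * cols
    lo, hi = 0.0, 2.0 + 1e-9
    for _ in range(60):
        t = (lo + hi) / 2
        if (ii + jj < t).sum() < target:
            lo = t
        else:
            hi = t
    m_lo = ii + jj < lo
    m_hi = ii + jj < hi
    return m_hi if abs(m_hi.sum() - target) <= abs(m_lo.sum() - target) else m_lo


def gen_bipartite_nested(
    rows: int, cols: int, fill: float, noise: float, seed: int
) -> Network:
    """Perfectly nested incidence at the target fill, then noisy cell flips.

    With noise=0 every defined pairwise overlap value is +1 (each row's
    partner set contains the next row's, so O = s_max for every pair);
    fill=1 gives the complete matrix where all pairs are degenerate (forced).
    Each cell is flipped independently with probability *noise*.
    """
    if rows <= 0 or cols <= 0:
        raise ParameterError("rows and cols must be positive")
    if not 0 < fill <= 1:
        raise ParameterError("fill must be in (0, 1]")
    if not 0 <= noise < 1:
        raise ParameterError("noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = _nested_mask(rows, cols, fill)
    if noise:
        flips = rng.random((rows, cols)) < noise
        mask = mask ^ flips
    return _bipartite_from_mask(_names(_ROW, rows), _names(_COL, cols), mask)


def gen_bipartite_modular(
    blocks: int, rows_per_block: int, cols_per_block: int, seed: int = 0
) -> Network:
    """Block-diagonal incidence, fully connected within blocks.

    The archetypal node-segregation regime: within-block row pairs overlap
    completely (+1), cross-block pairs share nothing (−1).  Deterministic;
    the seed is accepted for interface uniformity.
    """
    if blocks < 1 or rows_per_block <= 0 or cols_per_block <= 0:
        raise ParameterError("block counts and sizes must be positive")
    nr, nc = blocks * rows_per_block, blocks * cols_per_block
    mask = np.zeros((nr, nc), dtype=bool)
    for b in range(blocks):
        mask[
            b * rows_per_block : (b + 1) * rows_per_block,
            b * cols_per_block : (b + 1) * cols_per_block,
        ] = True
    return _bipartite_from_mask(_names(_ROW, nr), _names(_COL, nc), mask)


def gen_layered_foodweb(
    levels: int,
    species_per_level: int,
    down_link_prob: float = 0.5,
    skip_link_prob: float = 0.1,
    seed: int = 0,
) -> tuple[Network, dict[str, int]]:
    """Layered food web: level-0 basal, consumers draw prey from lower levels.

    Each consumer at level L takes each species at level L−1 as prey with
    probability *down_link_prob* (re-drawn until at least one such prey
    exists, so generator levels are recoverable) and each species below
    level L−1 with probability *skip_link_prob*.  Edges are stored
    resource→consumer.  Returns the network together with the generator's
    level map.
    """
    if levels < 2:
        raise ParameterError("need at least 2 levels")
    if species_per_level <= 0:
        raise ParameterError("species_per_level must be positive")
    if not 0 < down_link_prob <= 1:
        raise ParameterError("down_link_prob must be in (0, 1]")
    if not 0 <= skip_link_prob <= 1:
        raise ParameterError("skip_link_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [
        [f"L{l}N{k:02d}" for k in range(species_per_level)] for l in range(levels)
    ]
    gen_level = {v: l for l in range(levels) for v in names[l]}
    edges: list[tuple[str, str]] = []
    for l in range(1, levels):
        below = names[l - 1]
        deeper = [v for ll in range(l - 1) for v in names[ll]]
        for consumer in names[l]:
            prey = [u for u in below if rng.random() < down_link_prob]
            while not prey:  # every consumer needs ≥1 prey one level down
                prey = [u for u in below if rng.random() < down_link_prob]
            for u in prey:
                edges.append((u, consumer))
            for u in deeper:
                if rng.random() < skip_link_prob:
                    edges.append((u, consumer))
    net = Network(
        nodes=[v for lv in names for v in lv], edges=edges, directed=True
    )
    return net, gen_level


@dataclass(frozen=True)
class TaskWorldConfig:
    """Configuration of a task-matching host–parasite world.

    Sizes in the defaults' neighbourhood emulate digital co-evolution
    benchmarks (tens of hosts and parasites, a handful of task types).

    Parameters
    ----------
    n_hosts, n_parasites : int
        Guild sizes before isolated nodes are dropped.
    n_tasks : int
        Number of distinct trait/task tokens in the world.
    task_prob : float in (0, 1]
        Per-token inclusion probability when sampling a repertoire.  The
        default 0.45 with 6 tasks puts the mean permitted/complete partner
        ratio near 0.73, typical of trait-mediated host–parasite systems.
    realization : float in (0, 1]
        Probability that a permitted link is realized.
    structure : float in [−1, 1]
        Bias of realization *within* permitted sets: positive prefers
        high-permitted-degree hosts (nested realization), negative prefers
        hosts on the parasite's own task partition (segregated realization),
        0 is uniform.  Stands in for resource competition.
    seed : int
        Seed for the world's single random generator.
    """

    n_hosts: int = 20
    n_parasites: int = 20
    n_tasks: int = 6
    task_prob: float = 0.45
    realization: float = 0.5
    structure: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_hosts < 1 or self.n_parasites < 1 or self.n_tasks < 1:
            raise ParameterError("n_hosts, n_parasites, n_tasks must be positive")
        if not 0 < self.task_prob <= 1:
            raise ParameterError("task_prob must be in (0, 1]")
        if not 0 < self.realization <= 1:
            raise ParameterError("realization must be in (0, 1]")
        if not -1 <= self.structure <= 1:
            raise ParameterError("structure must be in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


_STRUCTURE_GAIN = 6.0  # log-odds span of the within-permitted realization bias


def gen_task_world(
    cfg: TaskWorldConfig,
) -> tuple[Network, TraitTable, PermittedInteractions]:
    """Sample one task-matching host–parasite world.

    Procedure: draw task repertoires (hosts may be taskless, parasite
    repertoires are resampled until non-empty); permit a link iff the two
    repertoires share ≥1 task; realize each parasite's permitted links —
    uniformly at ``structure=0``, else by weighted sampling without
    replacement of a Binomial(|permitted|, realization) number of hosts,
    weights exp(±gain·score) along the nested or partition axis.  At
    ``realization=1`` every permitted link is realized regardless of
    structure.  Nodes with no realized link are dropped (the emulated
    networks contain only interacting species); the returned permitted
    relation is restricted accordingly.
    """
    rng = np.random.default_rng(cfg.seed)
    tasks = [f"T{k}" for k in range(cfg.n_tasks)]
    hosts = _names("H", cfg.n_hosts)
    paras = _names("P", cfg.n_parasites)

    def draw_repertoire() -> frozenset[str]:
        return frozenset(t for t in tasks if rng.random() < cfg.task_prob)

    traits: dict[str, frozenset[str]] = {h: draw_repertoire() for h in hosts}
    for p in paras:
        rep = draw_repertoire()
        tries = 0
        while not rep:
            rep = draw_repertoire()
            tries += 1
            if tries > 1000:
                raise GenerationError("could not sample a non-empty parasite repertoire")
        traits[p] = rep

    # permitted[h][p] by task matching
    permitted_hosts = {
        p: [h for h in hosts if not traits[p].isdisjoint(traits[h])] for p in paras
    }
    if not any(permitted_hosts.values()):
        raise GenerationError("no permitted interaction exists (all repertoires disjoint)")

    host_perm_degree = {h: sum(h in ph for ph in permitted_hosts.values()) for h in hosts}
    # nested axis: global host rank by permitted degree, scaled to [0, 1]
    order = sorted(hosts, key=lambda h: (host_perm_degree[h], h))
    rank01 = {h: (k / (len(hosts) - 1) if len(hosts) > 1 else 1.0) for k, h in enumerate(order)}
    # segregation axis: a resource partition orthogonal to task matching, so
    # that the induced selectivity lives strictly *within* permitted sets
    # (ecological process) rather than in the permitted structure itself
    # (co-evolutionary constraint)
    part_of = {v: int(rng.integers(0, 2)) for v in hosts + paras}

    edges: list[tuple[str, str]] = []
    s = cfg.structure
    for p in paras:
        ph = permitted_hosts[p]
        if not ph:
            continue
        if cfg.realization == 1.0:
            chosen = ph
        elif s == 0.0:
            chosen = [h for h in ph if rng.random() < cfg.realization]
        else:
            k = rng.binomial(len(ph), cfg.realization)
            if k == 0:
                chosen = []
            else:
                if s > 0:
                    score = np.array([rank01[h] for h in ph])
                    logw = _STRUCTURE_GAIN * s * score
                else:
                    mine = part_of[p]
                    score = np.array([1.0 if part_of[h] == mine else 0.0 for h in ph])
                    logw = _STRUCTURE_GAIN * (-s) * score
                # Gumbel top-k = weighted sampling without replacement
                keys = logw + rng.gumbel(size=len(ph))
                chosen = [ph[t] for t in np.argsort(-keys)[:k]]
        edges.extend((h, p) for h in chosen)

    if not edges:
        raise GenerationError("no realized interaction; raise realization or sizes")

    linked = {v for e in edges for v in e}
    kept_hosts = [h for h in hosts if h in linked]
    kept_paras = [p for p in paras if p in linked]
    net = Network(
        nodes=kept_hosts + kept_paras,
        edges=edges,
        directed=False,
        bipartite_sides=(kept_hosts, kept_paras),
    )
    n = net.n_nodes
    m = np.zeros((n, n), dtype=bool)
    for p in kept_paras:
        jp = net.index(p)
        for h in permitted_hosts[p]:
            if h in linked:
                ih = net.index(h)
                m[ih, jp] = m[jp, ih] = True
    perm = PermittedInteractions(net.nodes, m, loops_allowed=False)
    table = TraitTable({v: traits[v] for v in net.nodes})
    return net, table, perm


def gen_task_world_series(
    n_networks: int,
    seed: int,
    host_range: tuple[int, int] = (6, 40),
    parasite_range: tuple[int, int] = (6, 40),
    n_tasks: int = 6,
    task_prob: float = 0.2,
    structure_range: tuple[float, float] = (0.0, -0.8),
    realization_range: tuple[float, float] = (0.95, 0.4),
) -> list[tuple[TaskWorldConfig, Network, TraitTable, PermittedInteractions]]:
    """A batch of task worlds spanning a diversity gradient.

    Guild sizes are drawn uniformly from the given ranges; the realization
    probability and the structure bias interpolate linearly with total
    diversity from the first to the second value of their ranges.  The
    defaults emulate the regime where species-poor worlds use essentially
    every host they can access (high realization, no within-permitted bias)
    while species-rich worlds differentiate host usage (lower realization,
    segregated realization within permitted sets) — host-use selectivity that
    only the constrained specification of n can reveal.
    """
    if n_networks < 1:
        raise ParameterError("n_networks must be positive")
    rng = np.random.default_rng(seed)
    lo = host_range[0] + parasite_range[0]
    hi = host_range[1] + parasite_range[1]
    out = []
    for _ in range(n_networks):
        nh = int(rng.integers(host_range[0], host_range[1] + 1))
        np_ = int(rng.integers(parasite_range[0], parasite_range[1] + 1))
        frac = ((nh + np_) - lo) / (hi - lo) if hi > lo else 0.0
        realization = realization_range[0] + frac * (
            realization_range[1] - realization_range[0]
        )
        structure = structure_range[0] + frac * (structure_range[1] - structure_range[0])
        cfg = TaskWorldConfig(
            n_hosts=nh,
            n_parasites=np_,
            n_tasks=n_tasks,
            task_prob=task_prob,
            realization=float(np.clip(realization, 0.05, 1.0)),
            structure=float(np.clip(structure, -1.0, 1.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for attempt in range(20):
            try:
                net, table, perm = gen_task_world(
                    TaskWorldConfig(**{**cfg.to_dict(), "seed": cfg.seed + attempt})
                )
                break
            except GenerationError:
                continue
        else:
            raise GenerationError("could not generate a valid task world in 20 attempts")
        out.append((cfg, net, table, perm))
    return out
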