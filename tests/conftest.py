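"""Shared fixtures: tiny networks with hand-enumerable overlap structure."""

from __future__ import annotations

import pytest

from nshare import Network


@pytest.fixture
def nested4x4() -> Network:
    """Perfectly nested 4x4 bipartite web: row k's partner set contains row k+1's."""
    rows = ["r1", "r2", "r3", "r4"]
    cols = ["c1", "c2", "c3", "c4"]
    edges = [
        ("r1", "c1"),
        ("r2", "c1"), ("r2", "c2"),
        ("r3", "c1"), ("r3", "c2"), ("r3", "c3"),
        ("r4", "c1"), ("r4", "c2"), ("r4", "c3"), ("r4", "c4"),
    ]
    return Network(rows + cols, edges, directed=False, bipartite_sides=(rows, cols))


@pytest.fixture
def modular2x2() -> Network:
    """Two fully connected 2x2 blocks: within-block overlap, cross-block segregation."""
    rows = ["r1", "r2", "r3", "r4"]
    cols = ["c1", "c2", "c3", "c4"]
    edges = [
        ("r1", "c1"), ("r1", "c2"), ("r2", "c1"), ("r2", "c2"),
        ("r3", "c3"), ("r3", "c4"), ("r4", "c3"), ("r4", "c4"),
    ]
    return Network(rows + cols, edges, directed=False, bipartite_sides=(rows, cols))


@pytest.fixture
def chain() -> Network:
    """Three-level food chain a -> b -> c (a basal; edges resource->consumer)."""
    return Network(["a", "b", "c"], [("a", "b"), ("b", "c")], directed=True)


def make_pair_web(d_i: int, d_j: int, n: int, overlap: int) -> Network:
    """Bipartite web with two focal rows of chosen degrees and shared-partner count.

    Row i uses partners p0..p(d_i-1); row j uses the last `overlap` of those
    plus fresh partners, inside a pool of n columns.
    """
    assert overlap <= min(d_i, d_j) and d_i + d_j - overlap <= n
    cols = [f"p{k}" for k in range(n)]
    edges = [("i", cols[k]) for k in range(d_i)]
    edges += [("j", cols[k]) for k in range(d_i - overlap, d_i - overlap + d_j)]
    return Network(
        ["i", "j"] + cols, edges, directed=False, bipartite_sides=(["i", "j"], cols)
    )
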