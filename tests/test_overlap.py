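"""Core metric: standardized pairwise overlap and the network mean."""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nshare import (
    Network,
    PermittedInteractions,
    connectance,
    gen_bipartite_bernoulli,
    mean_overlap,
    mean_shared_partners,
    pair_overlap,
    shareable_set,
)
from nshare.errors import ModeError, PairError, UnknownNodeError

from conftest import make_pair_web


# ---------------------------------------------------------------------------
# shareable sets
# ---------------------------------------------------------------------------

class TestShareableSet:
    def test_fully_permissive_excludes_both_focal_nodes(self):
        """With loops forbidden, any pair in a 6-node web can share n = 6 - 2 partners."""
        net = Network([f"v{k}" for k in range(6)], [], directed=True)
        perm = PermittedInteractions.fully_permissive(net)
        a = shareable_set(net, perm, "v0", "v1")
        assert len(a) == 4
        assert "v0" not in a and "v1" not in a

    def test_all_forbidden_gives_empty_set(self):
        net = Network(["a", "b", "c"], [], directed=True)
        assert shareable_set(net, PermittedInteractions.none_permitted(net), "a", "b") == frozenset()

    def test_trophic_style_intersection(self):
        """Only the common permitted resources of both consumers are shareable."""
        nodes = ["a", "b", "x", "i", "j"]
        net = Network(nodes, [], directed=True)
        m = np.zeros((5, 5), dtype=bool)
        idx = {v: k for k, v in enumerate(nodes)}
        for r, c in [("a", "i"), ("b", "i"), ("x", "i"), ("a", "j"), ("b", "j")]:
            m[idx[r], idx[c]] = True
        perm = PermittedInteractions(nodes, m)
        assert shareable_set(net, perm, "i", "j") == {"a", "b"}

    def test_errors(self):
        net = Network(["a", "b"], [], directed=True)
        perm = PermittedInteractions.fully_permissive(net)
        with pytest.raises(UnknownNodeError):
            shareable_set(net, perm, "a", "zz")
        undirected = Network(["a", "b"], [], directed=False)
        pu = PermittedInteractions.fully_permissive(undirected)
        with pytest.raises(ModeError):
            shareable_set(undirected, pu, "a", "b", direction="out")


# ---------------------------------------------------------------------------
# pairwise statistic
# ---------------------------------------------------------------------------

class TestPairOverlap:
    @pytest.mark.parametrize(
        "observed, value",
        [(2, 1.0), (1, 0.0), (0, -1.0)],
        ids=["complete-overlap", "at-expectation", "complete-segregation"],
    )
    def test_symmetric_triplet(self, observed, value):
        """d_i = d_j = 2, n = 4: the three canonical outcomes map to +1 / 0 / -1."""
        net = make_pair_web(2, 2, 4, observed)
        rec = pair_overlap(net, PermittedInteractions.fully_permissive(net), "i", "j",
                           direction="undirected")
        assert (rec.n, rec.d_i, rec.d_j, rec.observed) == (4, 2, 2, observed)
        assert rec.expected == 1.0
        assert rec.value == value

    def test_asymmetric_pair_with_enumeration_oracle(self):
        """d_i=3, d_j=2, n=4, O=2 saturates at +1; E matches exhaustive enumeration."""
        net = make_pair_web(3, 2, 4, 2)
        rec = pair_overlap(net, PermittedInteractions.fully_permissive(net), "i", "j",
                           direction="undirected")
        assert rec.expected == 1.5 and rec.s_max == 2 and rec.value == 1.0
        # oracle: mean shared count over all placements of a 2-subset vs fixed 3-subset
        pool = range(4)
        fixed = set(range(3))
        shared = [len(fixed & set(c)) for c in combinations(pool, 2)]
        assert Fraction(sum(shared), len(shared)) == Fraction(3 * 2, 4)

    def test_self_pair_rejected(self):
        net = make_pair_web(2, 2, 4, 1)
        with pytest.raises(PairError):
            pair_overlap(net, PermittedInteractions.fully_permissive(net), "i", "i",
                         direction="undirected")

    def test_degenerate_reasons(self):
        net = make_pair_web(2, 2, 4, 1)
        none = PermittedInteractions.none_permitted(net)
        rec = pair_overlap(net, none, "i", "j", direction="undirected")
        assert rec.degenerate and rec.reason == "empty-shareable-set"
        # zero realized degree
        cols = ["p0", "p1"]
        net2 = Network(["i", "j"] + cols, [("i", "p0")], directed=False,
                       bipartite_sides=(["i", "j"], cols))
        rec2 = pair_overlap(net2, PermittedInteractions.fully_permissive(net2), "i", "j",
                            direction="undirected")
        assert rec2.degenerate and rec2.reason == "zero-degree"
        # forced outcome: d_i = n
        net3 = make_pair_web(3, 2, 3, 2)
        rec3 = pair_overlap(net3, PermittedInteractions.fully_permissive(net3), "i", "j",
                            direction="undirected")
        assert rec3.degenerate and rec3.reason == "forced"
        assert rec3.s_min == rec3.s_max

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_bounds_saturation_and_symmetry(self, data):
        """Random pairs: value in [-1, 1]; +1 iff O=s_max>E; -1 iff O=s_min<E; i/j swap invariant."""
        n = data.draw(st.integers(1, 8))
        d_i = data.draw(st.integers(1, n))
        d_j = data.draw(st.integers(1, n))
        o = data.draw(st.integers(max(0, d_i + d_j - n), min(d_i, d_j)))
        net = make_pair_web(d_i, d_j, n, o)
        perm = PermittedInteractions.fully_permissive(net)
        rec = pair_overlap(net, perm, "i", "j", direction="undirected")
        rev = pair_overlap(net, perm, "j", "i", direction="undirected")
        assert (rev.n, rev.observed, rev.s_min, rev.s_max) == (rec.n, rec.observed, rec.s_min, rec.s_max)
        assert (rev.d_i, rev.d_j) == (rec.d_j, rec.d_i)
        if rec.degenerate:
            assert math.isnan(rec.value) and math.isnan(rev.value)
            return
        assert rev.value == rec.value
        assert -1.0 <= rec.value <= 1.0
        assert rec.s_min <= rec.observed <= rec.s_max
        assert (rec.value == 1.0) == (rec.observed == rec.s_max and rec.observed * n > d_i * d_j)
        assert (rec.value == -1.0) == (rec.observed == rec.s_min and rec.observed * n < d_i * d_j)


# ---------------------------------------------------------------------------
# network mean
# ---------------------------------------------------------------------------

class TestMeanOverlap:
    def test_nested_rows_all_positive(self, nested4x4):
        """Nested partner sets: every defined pairwise value is +1, so N-bar is +1."""
        s = mean_overlap(nested4x4, scope="rows")
        assert s.mean_overlap == 1.0
        defined = [p for p in s.pair_records if p.defined]
        assert defined and all(p.value == 1.0 for p in defined)
        # pairs involving the full row r4 (d = n) are forced, hence excluded
        assert s.n_pairs_excluded_degenerate == 3

    def test_modular_rows_minus_one_third(self, modular2x2):
        """2 within-block pairs at +1 and 4 cross-block pairs at -1 average to -1/3."""
        s = mean_overlap(modular2x2, scope="rows")
        assert s.n_pairs_included == 6
        assert s.mean_overlap == pytest.approx(-1 / 3, abs=1e-15)

    def test_single_includable_pair(self):
        net = make_pair_web(2, 2, 4, 2)
        s = mean_overlap(net, scope="rows")
        assert s.n_pairs_included == 1
        assert s.mean_overlap == 1.0

    def test_no_includable_pair_flagged_not_raised(self):
        net = Network(["r1", "r2", "c1"], [], directed=False,
                      bipartite_sides=(["r1", "r2"], ["c1"]))
        s = mean_overlap(net, scope="rows")
        assert not s.defined and math.isnan(s.mean_overlap)

    def test_degenerate_policy_zero_scores_forced_pairs(self, nested4x4):
        s = mean_overlap(nested4x4, scope="rows", degenerate_policy="zero")
        # 3 genuine +1 pairs and 3 forced pairs scored 0
        assert s.n_pairs_included == 6
        assert s.mean_overlap == pytest.approx(0.5)

    def test_scope_validation(self, nested4x4, chain):
        with pytest.raises(ModeError):
            mean_overlap(chain, scope="rows")
        with pytest.raises(ModeError):
            mean_overlap(nested4x4, scope="unimode-out")

    def test_restriction_consistency_with_direct_computation(self):
        """Fully permissive machinery agrees with a naive all-nodes set computation."""
        rng = np.random.default_rng(42)
        net = gen_bipartite_bernoulli(8, 9, 0.4, seed=3)
        s = mean_overlap(net, scope="rows")
        rows, cols = net.bipartite_sides
        n = len(cols)
        vals = []
        for i, j in combinations(sorted(rows), 2):
            pi, pj = net.partners(i, "undirected"), net.partners(j, "undirected")
            d_i, d_j, o = len(pi), len(pj), len(pi & pj)
            if d_i == 0 or d_j == 0:
                continue
            e = d_i * d_j / n
            s_min, s_max = max(0, d_i + d_j - n), min(d_i, d_j)
            if s_min == s_max:
                continue
            vals.append((o - e) / (s_max - e) if o >= e else (o - e) / (e - s_min))
        assert s.mean_overlap == pytest.approx(np.mean(vals), abs=1e-14)

    def test_order_independence(self, modular2x2):
        """N-bar does not depend on node declaration order."""
        perm_nodes = list(modular2x2.nodes)[::-1]
        shuffled = Network(perm_nodes, modular2x2.edges, directed=False,
                           bipartite_sides=modular2x2.bipartite_sides)
        a = mean_overlap(modular2x2, scope="rows").mean_overlap
        b = mean_overlap(shuffled, scope="rows").mean_overlap
        assert a == b

    def test_row_duplication_keeps_sign(self, nested4x4, modular2x2):
        """Duplicating every row's partner set never flips the sign of N-bar."""
        for net in (nested4x4, modular2x2):
            rows, cols = net.bipartite_sides
            dup_rows = list(rows) + [f"{r}_dup" for r in rows]
            edges = list(net.edges) + [
                (f"{u}_dup", v) if u in rows else (u, v) for u, v in net.edges
            ]
            dup = Network(dup_rows + list(cols), edges, directed=False,
                          bipartite_sides=(dup_rows, list(cols)))
            before = mean_overlap(net, scope="rows").mean_overlap
            after = mean_overlap(dup, scope="rows").mean_overlap
            assert math.copysign(1, before) == math.copysign(1, after)


class TestNullCalibration:
    def test_bernoulli_null_matches_exact_expectation(self):
        """Monte-Carlo means agree with exact enumeration: centered at c=0.5,
        negatively biased at c=0.2 (the below-expectation branch divides by the
        smaller bound, so sparse webs score segregated on average)."""
        from math import comb

        def exact_pair_mean(n, c):
            pb = [comb(n, d) * c**d * (1 - c) ** (n - d) for d in range(n + 1)]
            num = den = 0.0
            for di in range(1, n + 1):
                for dj in range(1, n + 1):
                    smin, smax = max(0, di + dj - n), min(di, dj)
                    if smin == smax:
                        continue
                    e, w, ev = di * dj / n, pb[di] * pb[dj], 0.0
                    for k in range(smin, smax + 1):
                        p = comb(di, k) * comb(n - di, dj - k) / comb(n, dj)
                        ev += p * ((k - e) / (smax - e) if k >= e else (k - e) / (e - smin))
                    num += w * ev
                    den += w
            return num / den

        assert exact_pair_mean(15, 0.5) == pytest.approx(0.0, abs=1e-12)
        for c in (0.2, 0.5):
            vals = [
                mean_overlap(gen_bipartite_bernoulli(15, 15, c, seed=9000 + r),
                             scope="rows", keep_pairs=False).mean_overlap
                for r in range(200)
            ]
            vals = np.array([v for v in vals if not math.isnan(v)])
            se = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - exact_pair_mean(15, c)) < 4 * se


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

class TestDiagnostics:
    def test_connectance(self, chain):
        two = Network(["r1", "r2", "c1", "c2"], [("r1", "c1"), ("r2", "c2")],
                      directed=False, bipartite_sides=(["r1", "r2"], ["c1", "c2"]))
        assert connectance(two) == 0.5
        full = Network(["r1", "r2", "c1", "c2"],
                       [(r, c) for r in ("r1", "r2") for c in ("c1", "c2")],
                       directed=False, bipartite_sides=(["r1", "r2"], ["c1", "c2"]))
        assert connectance(full) == 1.0
        assert connectance(chain) == pytest.approx(2 / 6)
        loopy = Network(["a", "b"], [("a", "a"), ("a", "b")], directed=True)
        assert connectance(loopy) == pytest.approx(1 / 2)  # loop dropped
        assert connectance(loopy, include_loops=True) == pytest.approx(2 / 4)
        assert math.isnan(connectance(Network([], [], directed=True)))

    def test_mean_shared_partners(self, modular2x2):
        cols = ["c1", "c2", "c3"]
        twin = Network(["r1", "r2"] + cols, [(r, c) for r in ("r1", "r2") for c in cols],
                       directed=False, bipartite_sides=(["r1", "r2"], cols))
        assert mean_shared_partners(twin, scope="rows") == 3.0
        assert mean_shared_partners(modular2x2, scope="rows") == pytest.approx(2 / 3)
        disjoint = Network(["r1", "r2", "c1", "c2"], [("r1", "c1"), ("r2", "c2")],
                           directed=False, bipartite_sides=(["r1", "r2"], ["c1", "c2"]))
        assert mean_shared_partners(disjoint, scope="rows") == 0.0
        single = Network(["r1", "c1"], [], directed=False,
                         bipartite_sides=(["r1"], ["c1"]))
        assert math.isnan(mean_shared_partners(single, scope="rows"))
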