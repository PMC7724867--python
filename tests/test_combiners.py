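"""The three divide-and-conquer combination rules against brute-force oracles."""

import math
import random

import pytest

from conftest import random_refined_costs
from dltrace.costs import CostModel, UNIT_COSTS
from dltrace.encoding import encode_pair
from dltrace.full_matrix import lw_full_matrix
from dltrace.linear import default_sentinel
from dltrace.oracle import enumerate_center_crossings
from dltrace.synth import random_pair
from dltrace.tracealg import (
    _backward_pass,
    _forward_pass,
    combine_cc_adjacent_A,
    combine_cc_adjacent_B,
    combine_no_cc,
)

INF = math.inf


def _passes(a, b, costs, engine="ls", q=3):
    pair = encode_pair(a, b)
    mid = pair.n // 2
    mv = default_sentinel(pair.m, pair.n, costs)
    fwd = _forward_pass(list(pair.A), list(pair.B[:mid]), pair.s, costs, mv, engine, q)
    bwd = _backward_pass(list(pair.A), list(pair.B[mid:]), pair.s, costs, mv, engine, q)
    return pair, mid, fwd, bwd


class TestNoCrossing:
    def test_explicit_sweep(self):
        # Forward row [0,1,2], backward [.,2,1,0] over A of length 2: every
        # split costs 2; ties resolve to the smallest i.
        cost, i = combine_no_cc([0, 1, 2], [None, 2, 1, 0], m=2)
        assert (cost, i) == (2, 0)

    def test_empty_A(self):
        cost, i = combine_no_cc([7], [None, 4], m=0)
        assert (cost, i) == (11, 0)

    def test_sentinel_propagation(self):
        big = 10**9
        cost, _ = combine_no_cc([big] * 3, [big] * 4, m=2)
        assert cost >= big

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_no_cc([0, 1, 2], [0, 1], m=2)

    def test_against_full_matrix_rows(self, rng):
        """Built from true prefix/suffix costs, the sweep minimum equals the
        brute-force minimum over all split points."""
        for _ in range(40):
            a, b = random_pair(12, rng.choice([2, 4]), rng)
            if len(b) < 3 or len(a) < 1:
                continue
            _, mid, (Rf, _, _), (Rb, _, _) = _passes(a, b, UNIT_COSTS)
            brute = min(Rf[i] + Rb[i + 1] for i in range(len(a) + 1))
            assert combine_no_cc(Rf, Rb, len(a))[0] == brute


class TestAdjacentB:
    def _brute(self, R1f, R1b, m, costs, ok1=None, ok2=None):
        ok1 = set(range(1, m + 1)) if ok1 is None else set(ok1)
        ok2 = set(range(1, m + 1)) if ok2 is None else set(ok2)
        best = (INF, None, None)
        for u1 in range(1, m + 1):
            for u2 in range(u1 + 1, m + 1):
                if u1 in ok1 and u2 in ok2:
                    tot = R1f[u1 - 1] + R1b[u2 + 1] + (u2 - u1 - 1) * costs.D + costs.T
                    if tot < best[0]:
                        best = (tot, u1, u2)
        return best

    def test_all_zero_arrays(self):
        cost, u1, u2 = combine_cc_adjacent_B([0] * 4, [0] * 5, m=3)
        assert (cost, u1, u2) == (1, 1, 2)  # minimise u2 - u1

    def test_too_short_gives_sentinel(self):
        cost, u1, u2 = combine_cc_adjacent_B([0, 0], [0, 0, 0], m=1)
        assert cost == INF and u1 is None and u2 is None

    def test_double_loop_oracle(self, rng):
        for _ in range(200):
            m = rng.randint(2, 12)
            R1f = [rng.randint(0, 20) for _ in range(m + 1)]
            R1b = [rng.randint(0, 20) for _ in range(m + 3)]
            costs = CostModel(1, 1, rng.choice([1, 2]), rng.choice([1, 2, 3]))
            ok1 = rng.sample(range(1, m + 1), rng.randint(0, m)) or None
            ok2 = rng.sample(range(1, m + 1), rng.randint(0, m)) or None
            got = combine_cc_adjacent_B(R1f, R1b, m, costs, ok1, ok2)
            want = self._brute(R1f, R1b, m, costs, ok1, ok2)
            assert got[0] == want[0], (R1f, R1b, costs, ok1, ok2)
            if got[0] != INF:
                # Same cost achieved at the reported pair.
                u1, u2 = got[1], got[2]
                assert (
                    R1f[u1 - 1] + R1b[u2 + 1] + (u2 - u1 - 1) * costs.D + costs.T
                    == got[0]
                )


class TestAdjacentA:
    def test_against_direct_eq_evaluation(self, rng):
        """The combiner value equals the direct full-matrix pricing of its
        candidates: u2 = u1+1, v2 the rightmost occurrence of A[u2] in the
        left half, v1 the leftmost occurrence of A[u1] in the right half."""
        checked = 0
        for trial in range(300):
            a, b = random_pair(12, rng.choice([2, 3, 4]), rng)
            m, n = len(a), len(b)
            if m < 2 or n < 3:
                continue
            costs = UNIT_COSTS if trial % 2 == 0 else random_refined_costs(rng)
            pair, mid, fwd, bwd = _passes(a, b, costs)
            got = combine_cc_adjacent_A(fwd[2], bwd[2], a, b, mid=mid, costs=costs)
            Hf = lw_full_matrix(a, b, costs=costs).H
            Hr = lw_full_matrix(a[::-1], b[::-1], costs=costs).H
            best = INF
            for u1 in range(1, m):
                u2 = u1 + 1
                v2 = max((v for v in range(1, mid + 1) if b[v - 1] == a[u2 - 1]), default=0)
                v1 = min((v for v in range(mid + 1, n + 1) if b[v - 1] == a[u1 - 1]), default=0)
                if not v2 or not v1:
                    continue
                suffix = Hr[m - u2][n - v1]  # cost of A[u2+1:] vs B[v1+1:]
                cand = Hf[u1 - 1][v2 - 1] + suffix + (v1 - v2 - 1) * costs.I + costs.T
                best = min(best, cand)
            assert got[0] == best, (a, b, mid, costs)
            checked += 1
        assert checked >= 100

    def test_missing_occurrences_give_sentinel(self):
        # A's characters never appear in the right half of B.
        pair, mid, fwd, bwd = _passes("aa", "aabb", UNIT_COSTS)
        got = combine_cc_adjacent_A(fwd[2], bwd[2], "aa", "aabb", mid=mid)
        assert got[0] == INF

    def test_tiny_B_gives_sentinel(self):
        got = combine_cc_adjacent_A([0, 0, 0], [0, 0, 0], "ab", "c", mid=0)
        assert got[0] == INF


class TestSplitSoundness:
    def test_three_way_minimum_is_optimal(self, rng):
        """At the root, min(no-crossing, B-adjacent, A-adjacent) equals the
        full-matrix optimum — both engines."""
        for trial in range(120):
            a, b = random_pair(14, rng.choice([2, 3, 4, 20]), rng)
            if len(b) < 3 or len(a) < 2:
                continue
            costs = UNIT_COSTS if trial % 2 == 0 else random_refined_costs(rng)
            want = lw_full_matrix(a, b, costs=costs).distance
            for engine in ("ls", "strip"):
                pair, mid, fwd, bwd = _passes(a, b, costs, engine=engine, q=2)
                c0, _ = combine_no_cc(fwd[0], bwd[0], len(a))
                ok1 = [u for u in range(1, len(a) + 1) if a[u - 1] == b[mid]]
                ok2 = [u for u in range(1, len(a) + 1) if a[u - 1] == b[mid - 1]]
                c1, _, _ = combine_cc_adjacent_B(fwd[1], bwd[1], len(a), costs, ok1, ok2)
                c2, _, _, _ = combine_cc_adjacent_A(
                    fwd[2], bwd[2], a, b, mid=mid, costs=costs
                )
                assert min(c0, c1, c2) == want, (a, b, costs, engine, c0, c1, c2)

    def test_engines_produce_identical_arrays(self, rng):
        """The transposed row-engine pass and the strip column-engine pass
        return the same boundary arrays."""
        for _ in range(60):
            a, b = random_pair(12, rng.choice([2, 4]), rng)
            if len(b) < 2:
                continue
            costs = random_refined_costs(rng)
            _, _, (Rf1, R1f1, FRf1), _ = _passes(a, b, costs, engine="ls")
            _, _, (Rf2, R1f2, FRf2), _ = _passes(a, b, costs, engine="strip", q=2)
            for q in range(-1, len(a) + 1):
                assert Rf1[q] == Rf2[q]
                assert R1f1[q] == R1f2[q]
                assert FRf1[q] == FRf2[q]


def test_center_crossing_enumeration_examples():
    # "ab" vs "ba" bisected at 1 contains the single-swap crossing of cost 1.
    found = enumerate_center_crossings("ab", "ba", mid=1)
    assert any(c[:4] == (1, 2, 2, 1) and c[4] == 1 for c in found)
    # No characters shared across the bisection: nothing to enumerate.
    assert enumerate_center_crossings("ab", "aabb", mid=2) == []
    # Any priced crossing is an upper bound on the distance.
    d = lw_full_matrix("ab", "ba").distance
    assert all(c[4] >= d for c in found)
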