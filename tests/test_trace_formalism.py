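import pytest

from dltrace.costs import CostModel, UNIT_COSTS
from dltrace.tracealg import (
    Trace,
    classify_lines,
    crossing_pairs,
    is_valid_trace,
    trace_to_edit_script,
)

A, B = "dafac", "fdbbec"
EXAMPLE = Trace.of({(1, 2), (3, 1), (4, 3), (5, 6)}, 5, 6)


class TestValidity:
    def test_worked_example_is_valid(self):
        assert is_valid_trace(EXAMPLE)

    def test_duplicate_endpoint_invalid(self):
        assert not is_valid_trace(Trace.of({(1, 1), (1, 2)}, 3, 3))
        assert not is_valid_trace(Trace.of({(1, 2), (3, 2)}, 3, 3))

    def test_out_of_bounds_invalid(self):
        assert not is_valid_trace(Trace.of({(6, 1)}, 5, 6))
        assert not is_valid_trace(Trace.of({(1, 0)}, 5, 6))


class TestClassification:
    def test_worked_example_partition(self):
        part = classify_lines(EXAMPLE, A, B)
        assert set(map(tuple, part.unbalanced)) == {(4, 3)}
        assert set(map(tuple, part.balanced)) == {(1, 2), (3, 1), (5, 6)}

    def test_empty_and_identity(self):
        empty = classify_lines(Trace.of(set(), 2, 2), "ab", "cd")
        assert empty.balanced == empty.unbalanced == frozenset()
        ident = classify_lines(Trace.of({(1, 1), (2, 2)}, 2, 2), "ab", "ab")
        assert len(ident.balanced) == 2 and not ident.unbalanced


class TestCrossings:
    def test_worked_example_single_crossing(self):
        pairs = crossing_pairs(EXAMPLE)
        assert {frozenset(map(tuple, p)) for p in pairs} == {
            frozenset({(1, 2), (3, 1)})
        }

    def test_monotone_trace_has_none(self):
        assert not crossing_pairs(Trace.of({(1, 1), (2, 3), (4, 5)}, 5, 6))

    def test_antidiagonal_all_cross(self):
        assert len(crossing_pairs(Trace.of({(1, 3), (2, 2), (3, 1)}, 3, 3))) == 3


class TestEditScript:
    def test_worked_example_script(self):
        """delete a_2, transpose a_1/a_3, substitute, two inserts, retain."""
        script = trace_to_edit_script(EXAMPLE, A, B)
        assert script.total_cost == 5
        assert script.apply(A) == B
        kinds = [op.op for op in script.ops]
        assert kinds.count("delete") == 1
        assert kinds.count("transpose") == 1
        assert kinds.count("substitute") == 1
        assert kinds.count("insert") == 2
        assert kinds.count("retain") == 1
        assert script.to_trace().lines == EXAMPLE.lines

    def test_weighted_cost(self):
        costs = CostModel(S=0.5, I=1, D=1, T=1)
        script = trace_to_edit_script(EXAMPLE, A, B, costs=costs)
        assert script.total_cost == 1 + 1 + 0.5 + 2 * 1  # D + T + S + 2I

    def test_empty_trace_is_delete_all_insert_all(self):
        script = trace_to_edit_script(Trace.of(set(), 2, 2), "ab", "cd")
        assert script.total_cost == 4
        assert script.apply("ab") == "cd"

    def test_identity_trace_costs_nothing(self):
        t = Trace.of({(i, i) for i in range(1, 5)}, 4, 4)
        script = trace_to_edit_script(t, "wxyz", "wxyz")
        assert script.total_cost == 0
        assert script.apply("wxyz") == "wxyz"

    def test_transposition_with_gap_characters(self):
        # A = a X b -> B = b Y a: crossing balanced pair with one delete (X)
        # inside A's gap and one insert (Y) inside B's gap.
        t = Trace.of({(1, 3), (3, 1)}, 3, 3)
        script = trace_to_edit_script(t, "aXb", "bYa")
        assert script.total_cost == 3  # delete + transpose + insert
        assert script.apply("aXb") == "bYa"

    def test_overlapping_crossings_rejected(self):
        t = Trace.of({(1, 3), (2, 2), (3, 1)}, 3, 3)
        with pytest.raises(ValueError, match="more than one crossing"):
            trace_to_edit_script(t, "abc", "cba")

    def test_unbalanced_crossing_rejected(self):
        t = Trace.of({(1, 2), (2, 1)}, 2, 2)
        with pytest.raises(ValueError, match="unbalanced"):
            trace_to_edit_script(t, "ab", "xy")

    def test_invalid_trace_rejected(self):
        with pytest.raises(ValueError, match="invalid trace"):
            trace_to_edit_script(Trace.of({(9, 1)}, 5, 6), A, B)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            trace_to_edit_script(EXAMPLE, "ab", "cd")
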