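# Methods

## The distance model

The unrestricted Damerau–Levenshtein (DL) distance between A = a₁…a_m and
B = b₁…b_n is the minimum total cost of an edit sequence of single-character
substitutions (cost S, charged only when the characters differ), insertions
(I), deletions (D) and transpositions of adjacent characters (T), applied to
an evolving copy of A until it equals B. Transpositions may act across a
gap: deleting the characters between a pair first, swapping the then-adjacent
pair, and refilling the gap with insertions afterwards is a single case of
the recurrence with cost (i−k−1)·D + T + (j−l−1)·I.

All algorithms here assume the *refined validity* condition

    2S ≤ I + D ≤ 2T,

satisfied in particular by the unit model S = I = D = T = 1. The right
inequality is the classical condition under which the four-case full-matrix
recurrence is exact; the left one is what licenses the refinement below. Cost
models violating the condition are rejected at entry with a diagnostic.

### The refined recurrence

In the full recurrence the transposition case consults H[k−1][l−1], where
k is the rightmost occurrence of bⱼ in A before row i and l the rightmost
occurrence of aᵢ in B before column j. Two observations prune it:

* if aᵢ = bⱼ, the transposition is useless (the matched pair already agrees),
  so one of the first three cases is at least as good;
* if aᵢ ≠ bⱼ and both i−k ≥ 2 and j−l ≥ 2, replacing the transposition by
  substitutions and insertions costs no more, because 2S ≤ I + D.

Hence the case is needed only when aᵢ ≠ bⱼ and min(i−k, j−l) = 1, i.e. when
one of the two matching occurrences is adjacent to the current cell. In that
situation the needed matrix entries are H[k−1][j−2] (when j−l = 1) and
H[i−2][l−1] (when i−k = 1) — close enough to the frontier to be carried in
linear space. For weighted costs the two branches contribute
H[k−1][j−2] + (i−k−1)·D + T and H[i−2][l−1] + (j−l−1)·I + T, which reduce to
the unit-cost forms H[k−1][j−2] + (i−k) and H[i−2][l−1] + (j−l).

## Linear-space distance (`ls_dl2`)

State while sweeping row i left to right:

* `R1[q] = H[i−1][q]`; `R[q] = H[i][q]` left of the cursor and `H[i−2][q]`
  at/right of it (the row two back is overwritten in place);
* `FR[q] = H[k−1][q−2]` for k the most recent row with A[k] = B[q] —
  refreshed exactly when a match A[i] = B[j] is seen, at which moment
  `R1[j−2]` holds the needed value;
* a scalar `T = H[i−2][l−1]` for l the most recent column of the current row
  with B[l] = A[i], refreshed from a one-cell-delayed copy of `R[j−1]`;
* `last_row_id[c]`: the last row whose A character is c.

The matrix is augmented with row −1 and column −1 filled with a sentinel
`maxVal`; all "occurrence does not exist" cases then resolve by sentinel
arithmetic instead of branches. Total DP storage is three (n+2)-arrays plus
one length-s table: Θ(m+n+s) elements (reported by the implementation in
`DLResult.allocated_cells` and asserted by the test suite on a 2000×2000
instance). On return, `R`, `R1`, `FR` hold row m, row m−1 and the final
helper row — the boundary data the trace recursion consumes.

### Sentinel choice

`maxVal` defaults to (m+n+1)·max(S,I,D,T,1)+1: strictly above any reachable
cell value (at most (m+n)·max-cost), and Python's unbounded integers /
double-precision sums keep sentinel arithmetic exact. A user-supplied
`maxVal` that fails to dominate is rejected. All comparisons are exact; with
integer costs every value is an integer, with float costs every value is a
finite sum of the inputs, so no tolerances are used anywhere.

## Strip computation (`strip_dl2`)

Columns 1..n are processed in ⌈n/q⌉ contiguous strips of width q (the last
one narrower when q ∤ n), each filled top-to-bottom with the row loop above
restricted to the strip, so the row arrays shrink to q+2 elements and stay
cache-resident. Three m-length column arrays carry state between strips:
`C` (rightmost computed column), `C1` (next-to-rightmost; both seed the
left-edge accesses of the next strip) and `FC[i] = H[i−2][l−1]` with l the
rightmost column so far whose B character equals A[i] (seeding the scalar
`T` per row). The weighted gap term (j−l−1)·I needs l itself, not just the
helper value, so the implementation carries the column indices l in a fourth
(integer) array alongside `FC`. `last_row_id` is rebuilt per strip as rows
restart; `FR` entries for a strip's columns are likewise rebuilt within the
strip, which is exact because they only reference rows above the cursor.

`choose_strip_width` picks the largest q whose modeled working set
3(q+2)+3(m+2) elements fits a given cache size; only the *fitting*
requirement is inherited, the working-set formula itself is this package's
model, and q can always be overridden on the CLI. Correctness never depends
on q: a property test asserts bit-identical distances for q ∈ {1, 2, 3,
⌈n/2⌉, n, n+5}.

## Optimal traces (`ls_trace2`, `strip_trace2`)

A trace is a set of lines (u, v), u a position of A and v of B, with
distinct endpoints on each side. Unattached A positions are deletions,
unattached B positions insertions, unbalanced lines (a_u ≠ b_v)
substitutions, balanced non-crossing lines free retains; a crossing pair of
balanced lines is a transposition with the intervening characters handled as
gap deletes/inserts. The minimum script cost over traces equals the DL
distance.

The recursion bisects B at mid = ⌊n/2⌋. A forward pass computes, for every
i, the optimal cost of A[1:i] vs B[1:mid]; a backward pass the cost of
A[i+1:m] vs B[mid+1:n] on the reversed strings. An optimal trace either has
no crossing straddling the bisection — then some split index i gives
cost R_f[i] + R_b[i+1] — or contains a *center crossing* {(u₁,v₁),(u₂,v₂)}
with v₂ ≤ mid < v₁ in canonical position (u₁ the rightmost occurrence of
b_{v₁} before u₂, v₂ the rightmost occurrence of a_{u₂} before v₁), which
forces u₂ = u₁+1 or v₁ = v₂+1:

* **B-adjacent** (v₂ = mid, v₁ = mid+1):
  min over u₁ < u₂ of R1_f[u₁−1] + R1_b[u₂+1] + (u₂−u₁−1)·D + T,
  restricted to u₁ with A[u₁] = B[mid+1] and u₂ with A[u₂] = B[mid]. The
  balancedness restriction is essential: the formula prices a realizable
  transposition only when both lines are balanced, and dropping the
  restriction can undercut the true distance (A = "ab", B = "cd" would
  price at 1 against a true distance of 2).
* **A-adjacent** (u₂ = u₁+1): for each u₁, v₂ is the rightmost occurrence
  of A[u₂] in B[1:mid] and v₁ the leftmost occurrence of A[u₁] in
  B[mid+1:n]; the cost FR_f[u₂] + FR_b[u₁] + (v₁−v₂−1)·I + T reads both
  terms directly off the transposition-helper arrays of the two passes.

Every candidate evaluated is the exact cost of some realizable trace (so
the minimum never undershoots), and the canonical form of an optimal trace
is always among the candidates (so it never overshoots); the test suite
verifies at every scale that the three-way minimum equals the full-matrix
optimum. The cheaper pass orientation differs by engine: the row engine runs
the DP transposed (rows = B-half, columns = A, insertion/deletion roles
swapped) so its final *row* arrays are indexed by A position; the strip
engine runs untransposed and its boundary *column* arrays C/C1/FC are the
same three quantities. A property test asserts the two engines produce
identical boundary arrays.

Design choices where the construction was genuinely open:

* **Backward re-indexing.** The backward pass runs on reversed strings and
  its arrays are re-indexed into original coordinates once, immediately
  (slot p = value for the suffix starting at p); all combiner formulas are
  then written in original coordinates.
* **Base case.** Subproblems with m ≤ 1 or n ≤ 2 are solved by full-matrix
  DP with backtracking; the submatrices are constant-width, so peak space
  stays Θ(m+n).
* **Tie-breaking.** Among equal-cost split kinds: no-crossing, then
  B-adjacent, then A-adjacent; within a kind the smallest index (u₁, then
  u₂). Purely for determinism; any choice is optimal.
* **Crossing recording.** At a center-crossing split the two lines are
  emitted and recursion continues on A[1:u₁−1]×B[1:v₂−1] and
  A[u₂+1:m]×B[v₁+1:n]; the characters strictly between stay unattached and
  become the transposition's gap deletes/inserts.
* **Script emission.** Operations are ordered by B coordinate with deletes
  placed where their A character falls, so `EditScript.apply` replays the
  script in one left-to-right pass (a transposition defers its second
  character until its gap insertions have been emitted).
* **Rejected traces.** `trace_to_edit_script` refuses traces in which a line
  participates in two crossings, or a crossing pair contains an unbalanced
  line: neither has an edit interpretation, and the algorithms never
  produce them.

## Independent oracle

`bfs_dl` computes the distance from its definition: cost-ordered (A*)
search over evolving strings with all four moves, visited-state dominance
pruning, and an admissible heuristic — a transposition can replace at most
two plain edits, so any state at Levenshtein distance L from B costs at
least L·min(S, I, D, T/2) more (L from edlib). It is deliberately capped at
length 8 and requires strictly positive costs (zero-cost moves would make
string space explode); it exists to certify the DP implementations on tiny
instances, not to scale. `enumerate_center_crossings` exhaustively lists
candidate center crossings on small instances and prices them from full
forward/backward matrices, as a brute-force check of the combiners.

## Synthetic data

`random_sequence` draws uniform i.i.d. letters, by default over the
20-letter amino-acid alphabet — the standard workload for benchmarking
these algorithms — with 2- and 4-letter alphabets available to emulate
binary/nucleotide data. Small alphabets are the stress case for
transpositions (repeated characters make crossings frequent); uniform
sequences lack the long repeats and local similarity of real genomic data,
so passing tests demonstrate algorithmic correctness on adversarially
transposition-rich inputs, not biological realism of the workload. Test
problem sizes (lengths up to 50 for the cross-implementation sweeps, 40 for
trace reconstruction, 7–8 for the string-space oracle, 2000×2000 for the
space contract) were chosen so the full suite exercises every code path —
multi-strip splits, center crossings of both kinds, degenerate and empty
inputs — while the oracle's exponential state space stays tractable.

## Known limitations

* O(mn) time is inherent to the recurrence; pure-Python throughput is a few
  million cells per second, fine up to a few thousand characters per side.
* Only the refined-validity cost regime is supported end to end; models with
  I + D ≤ 2T but 2S > I + D would need the unrefined recurrence in a
  non-constant-space variant and are out of scope (the full-matrix reference
  does accept them).
* One optimal trace is returned, not all co-optimal ones; which one depends
  on the documented tie-breaks.
* Multi-core variants and cache-miss/energy instrumentation are out of
  scope; `bench` reports wall time only.
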