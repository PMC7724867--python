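# dltrace

Linear-space computation of the **unrestricted Damerau–Levenshtein (DL)
distance** between two sequences, and reconstruction of an optimal **edit
trace** in the same space.

The DL distance is the minimum cost of transforming a string
A = a₁…a_m into B = b₁…b_n by single-character **substitutions** (cost S),
**insertions** (I), **deletions** (D) and **transpositions** of adjacent
characters (T). "Unrestricted" means a transposition may act across a gap:
the characters between the transposed pair are deleted first and the gap is
refilled by insertions afterwards, so transposed characters can end up far
apart. It is the natural distance for comparing DNA/RNA/protein sequences,
spelling correction, and read clustering, where all four operations occur.

## The algorithms

With H[i][j] the distance between prefixes A[1:i] and B[1:j], the classic
recurrence (valid when I + D ≤ 2T) is

    H[i][j] = min( H[i-1][j-1] + c(aᵢ,bⱼ),
                   H[i][j-1] + I,
                   H[i-1][j] + D,
                   H[k-1][l-1] + (i-k-1)·D + T + (j-l-1)·I )

where c(aᵢ,bⱼ) is S if aᵢ ≠ bⱼ and 0 otherwise, k is the rightmost
occurrence of bⱼ in A before i, and l the rightmost occurrence of aᵢ in B
before j. The transposition case makes the dependency structure non-local,
which is why standard linear-space tricks do not apply directly.

When additionally 2S ≤ I + D, the transposition case only ever helps if
aᵢ ≠ bⱼ **and** min(i−k, j−l) = 1 — otherwise plain substitutions and
insertions are at least as cheap. This *refined recurrence* needs only the
two previous rows plus two cheap helpers, giving:

* `ls_dl2` — the distance in Θ(m+n+s) space (s = alphabet size) and O(mn)
  time, using three (n+2)-length arrays;
* `strip_dl2` — the same DP swept in vertical strips of q columns for cache
  locality, passing three m-length boundary columns between strips;
* `ls_trace2` / `strip_trace2` — an optimal trace by Hirschberg-style
  bisection of B. A trace is a set of lines (u, v) pairing positions of A
  and B (distinct endpoints on each side); crossing balanced lines encode
  transpositions. Because an optimal trace may have a crossing that
  straddles the bisection column, each recursion step takes the cheapest of
  three combination rules: no straddling crossing, crossing with B-endpoints
  adjacent to the column, crossing with A-endpoints adjacent;
* `lw_full_matrix` / `refined_full_matrix` — O(mn)-space references;
* `bfs_dl` — an independent oracle that searches string space directly
  (tiny inputs only), used by the test suite to certify optimality.

## Worked example

The pair A = `dafac`, B = `fdbbec`:

```sh
$ dltrace dist --a dafac --b fdbbec --algorithm ls2
4
```

The optimum is 4: insert `f`, then substitute three characters. The optimal
trace and its edit script:

```sh
$ dltrace trace --a dafac --b fdbbec
distance        4
line    1       2       balanced
line    2       3       unbalanced
line    3       4       unbalanced
line    4       5       unbalanced
line    5       6       balanced
insert  1       f
retain  1       2       d
substitute      2       3       b
substitute      3       4       b
substitute      4       5       e
retain  5       6       c
script_cost     4
```

Each `line u v` row pairs A position u with B position v; balanced lines
(matching characters) cost nothing, unbalanced ones are substitutions, and
the script rows list the operations left to right. `script_cost` always
equals the distance.

A contrasting trace for the same pair — {(1,2), (3,1), (4,3), (5,6)} —
contains a crossing balanced pair {(1,2), (3,1)} and so encodes a gap
transposition: delete a₂, transpose a₁ and a₃, substitute b for a₄, insert
b₄ and b₅, retain a₅, for a total cost of 5. The library prices any such
trace via `trace_to_edit_script`.

Weighted costs (must satisfy 2S ≤ I + D ≤ 2T):

```sh
$ dltrace dist --a ab --b ba --costs 1,1.25,1.25,1.5
1.5
```

Here a single transposition (1.5) beats two substitutions (2.0). Random test
sequences come from `dltrace gen` (default: the 20-letter amino-acid
alphabet), and `dltrace bench` gives a quick O(mn) wall-time sanity check.

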