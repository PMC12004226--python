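# Methods

This note records the model implemented by `seqrex`, the numerical and design
choices that were genuinely open, what the synthetic data does and does not
emulate, and known limitations. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pattern grammar and dialects

The core grammar over an alphabet Σ (nucleotide `ACGT` or amino-acid
20-letter) has literals, concatenation, union, star and plus. Two user
dialects are expanded into it at parse time:

* **core** — standard regex syntax with grouping parentheses, `|`, postfix
  `*`/`+`, classes `[..]`, wildcards `_`/`.`, and bounded repeats `(n[,m])`
  (unambiguous because digits are not alphabet symbols);
* **prosite_like** — PROSITE notation: `-` separators (discarded), `x`
  wildcards, classes, negated classes `{..}` (complement over the alphabet),
  bounded repeats, and a tolerated trailing `.`.

All input is uppercased. Bounded repeats are macro-expanded into a union of
concatenation chains of n..m copies; the projected expansion size is capped
(default 10,000 tree nodes) and exceeding the cap is an error rather than a
silent rewrite. A lower repeat bound of 0 is rejected: the core AST has no
epsilon node, and none of the benchmark-style patterns require it — rewriting
`E(0,m)` by distributing the optional part into its context is left to the
user. N/C-terminus anchors are out of scope.

Two preconditions of the filter are enforced by `validate_for_k`: the
language must contain no word shorter than k (`MinLengthError` advises
lowering k or falling back to a plain scan), and no `*`/`+` operand may
accept the empty word (`EmptyRepeatError`).

## Graph construction

Postfix parsing drives a stack of (entry, exit) node-pair fragments, the
node-based analogue of Thompson's construction: character nodes spell one
symbol and have one outgoing arc; split nodes branch; join nodes merge. The
cyclic variant G is an NFA for L(R) and backs both bounded walk enumeration
and the verification matcher. The acyclic variant G^k replaces each repeat
by k−1 copies of its operand chained through split nodes s_1..s_{k−1} into a
join e:

* star: `s_i → a_i` (1 ≤ i ≤ k−1), `b_i → s_{i+1}` (1 ≤ i ≤ k−2),
  `s_i → e` (1 ≤ i ≤ k−1), `b_{k−1} → e`; fragment (s_1, e);
* plus: identical but entered at `a_1`, with splits s_2..s_{k−1} only;
  fragment (a_1, e).

This wiring yields **exactly one** walk per repetition count (0..k−1 for
star, 1..k−1 for plus). The alternative of adding direct early-exit arcs
`b_i → e` for i < k−1 duplicates walks with identical words and k-mer sets
and would double-count paths in the complexity DP, so it is not used. The
first copy reuses the operand subgraph; further copies are deep clones with
fresh ids; node ids follow creation order and break all ties, making
construction and traversal fully deterministic. Degenerate unrolls at k = 1
(a single pass-through join for star, the bare operand for plus) only drop
k-mer requirements and therefore keep the filter sound.

## Collection phase

An array A holds one insertion-ordered map per node, keyed by the rightmost
k−1 buffer symbols. A[s] starts as `{-^(k-1) -> [-^k, 1^u]}`; gaps occupy a
prefix of the buffer until k symbols have been spelled, and `update` fires
only on gap-free buffers, so the first k−1 character nodes are traversed
unqueried. Character nodes leftshift/update/push to their single successor;
split nodes copy entries to every successor and clear; entry/join nodes
move entries onward; the exit node ORs the surviving bitvectors. `absorb`
(bitvector OR, first buffer symbol masked) is exact, not heuristic: two
entries with the same suffix at the same node share their entire future, and
AND distributes over OR — the regular suite and the acceptance suite verify
equality with explicit walk enumeration on hundreds of random (regex,
corpus) pairs. Reported statistics (index queries, absorptions, prunings,
peak live entries) are deterministic because map iteration follows insertion
order.

## k-mer complexity

`c_k` is computed by one topological sweep over a node × k matrix: at a
character node the row shifts right, column 0 becomes 1, the last column is
appended to v, and every node adds its row to its direct successors. v[i]
equals the number of directed paths with exactly k character nodes ending at
character node i (verified against exhaustive path enumeration). For a pure
concatenation of residue classes the identity reduces to a sum of window
products of class sizes; for the PROSITE aspartyl-protease signature
PS00141 (class sizes 8,8,6,1,2,1,4,8,18,9,17,8) this gives c_5 = 271,696 and
c_6 = 806,208, which the acceptance script recomputes from the pattern text.

## Index

A flat interleaved Bloom filter is used: a (bits_per_bin × u) bit matrix
whose rows are u-bit slices, so a query reads h rows and ANDs them. The
hierarchical layout is an optimization of the same query contract for many
or uneven bins and is out of scope. Sizing inverts
`(1 − e^(−h·n/m))^h ≤ p` for the fullest bin (default p = 0.05, h = 3).
Hashing packs a k-mer into 64 bits (2 bits/nucleotide, 5 bits/residue —
capping k at 32 and 12 respectively) and derives h positions by double
hashing with two seeded splitmix64 values, `pos_i = (h1 + i·h2) mod m`;
scalar and vectorized paths are tested for agreement. k-mers are indexed as
written (no reverse-complement canonicalization): strand handling is a
query-side concern. Serialization is a versioned binary file (magic, JSON
header with all parameters and bin names, packed bit matrix); loads reject
truncation and version mismatches, and a reloaded index enforces its own k.

`ExactKmerIndex` (per-bin hash sets of packed k-mers) implements the same
query interface with zero false positives — the p → 0 limit — and serves as
the reference oracle and as an exact backend for small databases.

## Verification matcher

Verification uses the package's own NFA simulation over G rather than a
delegated engine, so the reported semantics are fully specified: at every
start position the longest match is reported; overlapping starts are all
reported; record lines are concatenated, so matches may span line breaks.
Subset transitions are memoized lazily (a lazy-DFA), keeping the scan linear
in practice. Agreement with a brute-force longest-match oracle built on
Python `re` is tested on random patterns and texts. Reverse-strand matches
are found by scanning the forward text with the reverse-complement pattern
(an involution, tested) and are reported with forward-text coordinates and
the minus-strand sequence as matched text. DNA queries search both strands
by default (`--no-revcomp` disables).

## Synthetic data

`default_nucleotide_spec` emulates a randomized nucleotide experiment at
1/1000 of the published scale, chosen once as this package's study
conditions: 2^6 bins × 2^16 characters (one record per bin, 70-character
lines), i.i.d. uniform background, k = 13, five patterns of minimum length
≥ 13 — four planted twice each (one instance within a line, one forced to
cross a line break), one never planted. Planted words are sampled uniformly
per union branch with geometric repetition counts (p = 0.5, capped at 2k) at
uniform non-overlapping offsets; a truth TSV records every plant. Given a
seed the corpus is byte-identical.

What the generator does **not** emulate: real base composition and repeat
structure, multi-record bins, ambiguity codes, and uneven bin sizes. Passing
tests therefore demonstrate correctness of the filtering logic and
exactness of the collection algebra, not retrieval performance on real
genomes; on low-complexity real text the filter will flag more bins.

## Known limitations and deviations

* **Per-walk covering of mixed repetitions fails.** The guarantee "every
  cyclic walk has an unrolled walk whose k-mer set it contains" is false
  when a union-bearing repeat is traversed ≥ k times with mixed
  alternatives: for `CG(A|TT)*GC`, k = 3, the walk spelling `CGATTAGC`
  (choices A, TT, A) has k-mers {CGA, GAT, ATT, TTA, TAG, AGC}, and each of
  the seven unrolled walks requires a boundary k-mer (CGT, GAG, GAA, TTG,
  TGC, ...) that this walk never spells. Consequently the filter can, on a
  text containing essentially only such an occurrence, fail to flag its bin.
  The property does hold when repeat operands are single words (tested), and
  the default synthetic patterns use only such repeats. One acceptance test
  asserts the claimed general form and fails, documenting the gap.
* **The four-bin worked example's "false positive" bin is real.** For
  R = `A(A|C|G)(C|G)C(T)*A`, the bin AAGCCA contains AGCCA ∈ L(R)
  (independently confirmed with `grep -E` and Python `re`), so a correct
  verifier reports a match there; the corresponding narrative assertion is
  kept as stated and fails.
* Bloom sizing note: "one bit suffices as p → 1" holds only in the strict
  limit; for any fixed p < 1 and large h·n the closed form requires m > 1.
* Bounded repeats are always macro-expanded; native min-max matching (e.g.
  testing two substrings at a distance, useful for patterns like
  `N-G-x-[DE](2)-x-[LIVMF]-C-[ST]-x(11,12)-[PAG]-D`) is not implemented, so
  patterns with very wide bounds hit the expansion cap by design.
* Problem sizes in the default test and acceptance runs (corpus scale,
  numbers of random trials) are the package's chosen study conditions; the
  generator itself scales to arbitrarily large corpora.
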