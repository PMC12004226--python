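# seqrex

Index-accelerated regular-expression search over binned biological sequence
databases.

Highly conserved DNA and protein motifs — transcription-factor binding sites,
PROSITE-style active-site signatures — are naturally written as regular
expressions: `[TC]-A-A-T-[TC]-[AT]` for a homeodomain binding site, or
`[LIVM]-[ST]-A-[STAG]-H-C` for the trypsin histidine active site. Scanning a
multi-gigabyte FASTA database for such a pattern with a conventional regex
engine is linear in the text, which is far too slow for interactive use.
`seqrex` implements a filter-then-verify strategy: an **interleaved Bloom
filter (IBF)** k-mer index narrows the search to the handful of database
*bins* that could possibly contain a match, and only those bins are scanned.

## The method

1. **Binning and indexing.** The database is split into *u* FASTA files
   ("user bins"). Every length-*k* window of every record (windows span line
   breaks, never record boundaries; windows with ambiguity codes are skipped)
   is hashed with *h* seeded hash functions into that bin's Bloom filter. The
   *u* filters are stored interleaved, so one k-mer query returns a *u*-bit
   **binning bitvector** — bit *j* set means bin *j* (probably) contains the
   k-mer, with a user-chosen false-positive rate *p* and no false negatives.

2. **The k-graph G^k.** The query regex *R* — literals, concatenation, union
   `|`, star `*`, plus `+`, after expansion of classes `[..]`, wildcards, and
   bounded repeats `(n,m)` — is converted to postfix (shunting-yard) and
   compiled into a node-based Thompson-style automaton in which every `*`/`+`
   operand is unrolled *k−1* times behind split nodes. The result is an
   **acyclic** graph whose (s,t)-walks spell words of *L(R)* carrying the
   k-mers needed to witness a match. Preconditions: *L(R)* contains no word
   shorter than *k*, and no repeat operand accepts the empty word.

3. **Collection.** G^k is traversed once in topological order, maintaining
   entries `[n, s, b]` (next node, k-symbol buffer, binning bitvector). A
   character node shifts its symbol into the buffer and, when the buffer is
   complete, ANDs the bitvector with the index answer (`update`); all-zero
   entries are pruned; entries colliding on the same (k−1)-suffix at a node
   are merged by OR (`absorb`). The surviving bins at the exit node equal
   `OR over walks (AND over the walk's k-mers)` — a necessary condition for
   a match.

4. **Verification.** Only positive bins are opened and scanned linearly with
   an NFA matcher (longest match at every start position; for DNA the
   reverse strand is searched by default via the reverse-complement pattern).

The predicted traversal cost is the **k-mer complexity**
`c_k = Σ_i v_i`, where `v_i` counts directed paths with exactly *k*
character nodes ending at character node *i* — computed by a single
dynamic-programming sweep (`seqrex complexity`).

## Worked example

Simulate a small corpus (8 bins × 4,096 nt, planted motif instances), index
it, and search:

```sh
$ seqrex --quiet simulate --bins 8 --chars 4096 -k 13 --seed 4 -o corpus
$ seqrex index -k 13 --fpr 0.05 -o db.ibf corpus/bin_*.fa
INFO indexed 8 bins (k=13, 26664 bits/bin) -> db.ibf
$ seqrex query -i db.ibf -p "GAT(CA)+TTACGGAT"
INFO GAT(CA)+TTACGGAT: 2/8 positive bins (25.0% scanned), 2 matches, 13 index queries
bin_name  record_id  start0  end0  start1  end1  strand  matched_text
bin_002   seq_002    3951    3964  3952    3964  +       GATCATTACGGAT
bin_005   seq_005    1954    1967  1955    1967  +       GATCATTACGGAT
```

Only 2 of 8 bins were scanned, and both planted instances of the pattern
(`corpus/truth.tsv`) were recovered. Coordinates are given 0-based half-open
(`start0`,`end0`) and 1-based inclusive (`start1`,`end1`). The k-mer
complexity report for a pattern:

```sh
$ seqrex --quiet complexity -k 3 -p "A(A|G)CCT*A"
v = [0, 0, 0, 2, 2, 1, 1, 3]
c_3 = 9
```

Each entry of `v` is the number of 3-mers completed at one character node of
the unrolled graph (in topological order); their sum `c_3` is the total
number of distinct 3-mer paths the collection phase may have to query.

The same pipeline is available as a library: `expand_pattern` /
`validate_for_k` / `build_graph` / `collect_positive_bins` / `run_query`,
with `ExactKmerIndex` as a zero-false-positive reference index.

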