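"""Verification stage: linear regex scan of candidate bins.

Only bins flagged positive by the collection phase are opened. Each FASTA
record's lines are concatenated before matching, so occurrences may span the
original line breaks. The matcher is a bespoke Thompson-style NFA simulation
over the cyclic node graph G (lazily memoized subset transitions), with
fully pinned semantics: at every start position the longest match, if any, is
reported; overlapping starts are all reported. For DNA the reverse strand is
searched by scanning the forward text with the reverse-complement pattern and
reporting minus-strand records with forward-text coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .alphabet import DNA_COMPLEMENT, reverse_complement
from .collect import CollectStats, collect_positive_bins
from .errors import AlphabetError
from .ibf import Bitvector
from .kgraph import CHARACTER, KGraph, build_graph
from .regexes import (Alt, Cat, CoreRegex, Lit, Plus, Star, expand_pattern,
                      to_postfix, validate_for_k)


def reverse_complement_regex(r: CoreRegex) -> CoreRegex:
    """Mirror the tree and complement every literal; L(out) = revcomp(L(r))."""
    if isinstance(r, Lit):
        if r.char not in DNA_COMPLEMENT:
            raise AlphabetError("reverse-complement is defined for DNA patterns only")
        return Lit(DNA_COMPLEMENT[r.char])
    if isinstance(r, Cat):
        return Cat(reverse_complement_regex(r.right), reverse_complement_regex(r.left))
    if isinstance(r, Alt):
        return Alt(reverse_complement_regex(r.left), reverse_complement_regex(r.right))
    if isinstance(r, Star):
        return Star(reverse_complement_regex(r.child))
    if isinstance(r, Plus):
        return Plus(reverse_complement_regex(r.child))
    raise TypeError(f"not a CoreRegex node: {r!r}")


class NFAMatcher:
    """Longest-match NFA simulation over the cyclic graph G for a pattern."""

    def __init__(self, r: CoreRegex):
        self.g: KGraph = build_graph(to_postfix(r), k=1, variant="G")
        g = self.g
        self._char: list[Optional[str]] = [n.char for n in g.nodes]
        # For each node: character nodes reachable from its successors through
        # non-character nodes, and whether the exit t is so reachable.
        self._next: list[tuple[frozenset[int], bool]] = [
            self._closure(g.succ(v)) for v in range(len(g.nodes))]
        self.start, self.start_accept = self._next[g.s]
        self._trans: dict[tuple[frozenset[int], str], tuple[frozenset[int], bool]] = {}

    def _closure(self, seeds: Sequence[int]) -> tuple[frozenset[int], bool]:
        chars: set[int] = set()
        accept = False
        stack = list(seeds)
        seen: set[int] = set()
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            if self.g.node(v).kind == CHARACTER:
                chars.add(v)
            elif v == self.g.t:
                accept = True
            else:
                stack.extend(self.g.succ(v))
        return frozenset(chars), accept

    def _step(self, state: frozenset[int], c: str) -> tuple[frozenset[int], bool]:
        key = (state, c)
        hit = self._trans.get(key)
        if hit is not None:
            return hit
        nxt: set[int] = set()
        accept = False
        for v in state:
            if self._char[v] == c:
                more, acc = self._next[v]
                nxt |= more
                accept = accept or acc
        out = (frozenset(nxt), accept)
        self._trans[key] = out
        return out

    def longest_match(self, text: str, start: int) -> Optional[int]:
        """End of the longest match beginning at ``start``, or None."""
        state = self.start
        best = start if self.start_accept else -1
        j = start
        n = len(text)
        while j < n and state:
            state, accept = self._step(state, text[j])
            j += 1
            if accept:
                best = j
        return best if best >= 0 else None

    def finditer(self, text: str):
        """Yield (start, end) of the longest match at every matching start."""
        for i in range(len(text)):
            end = self.longest_match(text, i)
            if end is not None and end > i:
                yield i, end


@dataclass(frozen=True)
class MatchRecord:
    bin_index: int
    bin_name: str
    record_id: str
    start: int              # 0-based half-open forward-text coordinates
    end: int
    strand: str             # "+" or "-"
    matched_text: str       # the sequence on the reported strand


@dataclass
class QueryReport:
    pattern: str
    k: int
    positive_bins: Bitvector
    matches: list[MatchRecord]
    stats: CollectStats
    filter_only: bool = False

    @property
    def scanned_fraction(self) -> float:
        return self.positive_bins.count() / self.positive_bins.u

    def to_tsv(self) -> str:
        lines = ["bin_name\trecord_id\tstart0\tend0\tstart1\tend1\tstrand\tmatched_text"]
        for m in self.matches:
            lines.append(f"{m.bin_name}\t{m.record_id}\t{m.start}\t{m.end}"
                         f"\t{m.start + 1}\t{m.end}\t{m.strand}\t{m.matched_text}")
        return "\n".join(lines) + "\n"

    def to_bed(self, name: str = "pattern") -> str:
        lines = []
        for m in self.matches:
            lines.append(f"{m.record_id}\t{m.start}\t{m.end}\t{name}\t0\t{m.strand}")
        return "\n".join(lines) + ("\n" if lines else "")


def scan_records(records: Sequence[tuple[str, str]], r: CoreRegex,
                 strand_mode: str = "forward", bin_index: int = 0,
                 bin_name: str = "") -> list[MatchRecord]:
    """Scan in-memory (id, sequence) records; lines are already concatenated."""
    matchers = [("+", NFAMatcher(r))]
    if strand_mode == "both":
        matchers.append(("-", NFAMatcher(reverse_complement_regex(r))))
    elif strand_mode != "forward":
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    out: list[MatchRecord] = []
    for rid, seq in records:
        seq = seq.upper()
        for strand, matcher in matchers:
            for i, j in matcher.finditer(seq):
                text = seq[i:j] if strand == "+" else reverse_complement(seq[i:j])
                out.append(MatchRecord(bin_index, bin_name, rid, i, j, strand, text))
    return out


def scan_bin(path: str | Path, r: CoreRegex, strand_mode: str = "forward",
             bin_index: int = 0, bin_name: str | None = None) -> list[MatchRecord]:
    """Linear scan of one FASTA bin for all leftmost-longest occurrences."""
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return scan_records(records, r, strand_mode, bin_index,
                        bin_name if bin_name is not None else path.stem)


def run_query(index, pattern: str, bin_paths: Sequence[str | Path] | None = None,
              dialect: str = "core", strand_mode: str | None = None,
              filter_only: bool = False, expansion_cap: int = 10_000) -> QueryReport:
    """Full pipeline: parse -> build G^k -> collect positive bins -> verify.

    ``index`` is an IBF or exact index; bins not flagged positive are never
    opened. DNA queries search both strands by default.
    """
    alphabet = index.alphabet.name
    if strand_mode is None:
        strand_mode = "both" if alphabet == "dna" else "forward"
    if strand_mode == "both" and alphabet != "dna":
        raise AlphabetError("reverse-strand search applies to DNA only")
    r = expand_pattern(pattern, dialect=dialect, alphabet=alphabet,
                       expansion_cap=expansion_cap)
    validate_for_k(r, index.k)

    gk = build_graph(to_postfix(r), index.k, "Gk")
    positive, stats = collect_positive_bins(gk, index)
    if strand_mode == "both":
        rc = reverse_complement_regex(r)
        gk_rc = build_graph(to_postfix(rc), index.k, "Gk")
        positive_rc, stats_rc = collect_positive_bins(gk_rc, index)
        positive = positive | positive_rc
        stats.kmer_queries += stats_rc.kmer_queries
        stats.entries_absorbed += stats_rc.entries_absorbed
        stats.entries_pruned += stats_rc.entries_pruned
        stats.max_live_entries = max(stats.max_live_entries, stats_rc.max_live_entries)

    matches: list[MatchRecord] = []
    if not filter_only:
        paths = list(bin_paths) if bin_paths is not None else list(index.bin_paths)
        if len(paths) != index.u:
            raise ValueError(f"{len(paths)} bin paths for a {index.u}-bin index")
        for j in positive.indices():
            matches.extend(scan_bin(paths[j], r, strand_mode, j, index.bin_names[j]))
    return QueryReport(pattern=pattern, k=index.k, positive_bins=positive,
                       matches=matches, stats=stats, filter_only=filter_only)
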