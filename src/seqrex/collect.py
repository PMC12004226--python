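"""The collection phase: topological traversal of G^k against the k-mer index.

Walk states are *entries* ``[n, s, b]``: the node the walk is about to leave,
a k-symbol buffer (gaps ``-`` form a prefix until the first k symbols have
been spelled), and a binning bitvector of bins that still hold every complete
k-mer spelled so far. Visiting a character node leftshifts the buffer by the
spelled symbol and, once the buffer is gap-free, ANDs the bitvector with the
index answer for that k-mer (dead entries — all-zero — are pruned). Entries
are keyed by their (k-1)-suffix; two entries colliding at the same node are
*absorbed* into one (bitvector OR, first buffer symbol masked), which is
exact because entries at the same node with the same suffix share their
entire future. The bins surviving at the exit node are exactly

    OR over (s,t)-walks of (AND over the walk's complete k-mers of the
    index's binning bitvectors),

a necessary condition for a match, never missing a bin that contains one,
provided some walk's k-mer set is covered by the matching text.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .errors import IndexMismatchError
from .kgraph import CHARACTER, EXIT, SPLIT, KGraph
from .ibf import Bitvector

GAP = "-"


@dataclass(frozen=True)
class Entry:
    """One traversal state: next node, k-symbol buffer, binning bitvector."""

    n: int
    s: str
    b: Bitvector

    @property
    def key(self) -> str:
        return self.s[1:]

    @property
    def complete(self) -> bool:
        return GAP not in self.s

    def __str__(self) -> str:
        return f"[{self.n}, {self.s}, {self.b}]"


def leftshift(e: Entry, c: str) -> Entry:
    """Shift the buffer left one position and append the spelled symbol."""
    return Entry(e.n, e.s[1:] + c, e.b)


def update(e: Entry, idx) -> Optional[Entry]:
    """AND the bitvector with the index answer for the (complete) buffer.

    Returns None when the result is all-zero: the walk prefix cannot lie in
    any bin and the entry is discarded.
    """
    assert e.complete, "update requires a gap-free k-mer buffer"
    b = e.b & idx.query_kmer(e.s)
    if not b.any():
        return None
    return Entry(e.n, e.s, b)


def absorb(e1: Entry, e2: Entry) -> Entry:
    """Merge two entries that collided on the same key at the same node."""
    if e1.key != e2.key or e1.n != e2.n:
        raise ValueError(f"absorb precondition violated: {e1} vs {e2}")
    return Entry(e1.n, GAP + e1.key, e1.b | e2.b)


@dataclass
class CollectStats:
    kmer_queries: int = 0
    entries_absorbed: int = 0
    entries_pruned: int = 0
    max_live_entries: int = 0


def collect_positive_bins(g: KGraph, idx,
                          trace: Optional[Callable[[str], None]] = None
                          ) -> tuple[Bitvector, CollectStats]:
    """Compute the binning bitvector of bins that may contain a match.

    ``idx`` is any object with ``k``, ``u`` and ``query_kmer``; its k must
    equal the graph's. The returned vector is a superset of the true-match
    bins whenever the index has no false negatives.
    """
    if g.variant != "Gk":
        raise ValueError("collection requires the acyclic variant G^k")
    if idx.k != g.k:
        raise IndexMismatchError(f"index k = {idx.k} but graph k = {g.k}")
    u = idx.u
    stats = CollectStats()

    A: dict[int, dict[str, Entry]] = {i: {} for i in range(len(g.nodes))}

    def push(target: int, e: Entry) -> None:
        e = Entry(target, e.s, e.b)
        amap = A[target]
        old = amap.get(e.key)
        if old is None:
            amap[e.key] = e
        else:
            amap[e.key] = absorb(old, e)
            stats.entries_absorbed += 1

    A[g.s] = {GAP * (g.k - 1): Entry(g.s, GAP * g.k, Bitvector.ones(u))}
    result = Bitvector.zeros(u)

    for i in g.topo:
        entries = list(A[i].values())
        A[i] = {}
        if not entries:
            continue
        stats.max_live_entries = max(stats.max_live_entries, len(entries))
        node = g.node(i)
        if trace is not None:
            trace(f"node {i} ({node.kind}{'/' + node.char if node.char else ''}): "
                  + " ".join(map(str, entries)))
        if node.kind == CHARACTER:
            (succ,) = g.succ(i)
            for e in entries:
                e = leftshift(e, node.char)
                if e.complete:
                    stats.kmer_queries += 1
                    e = update(e, idx)
                    if e is None:
                        stats.entries_pruned += 1
                        continue
                push(succ, e)
        elif node.kind == SPLIT:
            for succ in g.succ(i):
                for e in entries:
                    push(succ, e)
        elif node.kind == EXIT:
            # the unique final exit node: report surviving bins
            for e in entries:
                result = result | e.b
        else:  # entry node s or a join node: move entries onward
            (succ,) = g.succ(i)
            for e in entries:
                push(succ, e)
    return result, stats
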