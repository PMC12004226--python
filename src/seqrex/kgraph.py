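"""Node-based automata for regex filtering: the cyclic graph G and the
acyclic k-graph G^k.

G is a node-based Thompson-style NFA for the pattern: character nodes spell
one symbol each and have exactly one outgoing arc; split nodes branch; join
nodes merge. G^k replaces every * / + subgraph by k-1 chained copies of its
operand, so the graph is acyclic yet still spells, along its (s,t)-walks,
words whose k-mers cover every k-mer needed to witness a match (boundary
k-mers of longer repetitions are already produced by k-1 unrollings).

The k-mer complexity c_k — the number of directed paths in G^k containing
exactly k character nodes — predicts traversal cost and is computed by a
single dynamic-programming sweep in topological order.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

from .errors import CycleError, PostfixError, WalkBudgetExceeded
from .regexes import CONCAT

CHARACTER = "character"
SPLIT = "split"
JOIN = "join"
ENTRY = "entry"
EXIT = "exit"


@dataclass(frozen=True)
class KNode:
    id: int
    kind: str
    char: Optional[str] = None


@dataclass
class KGraph:
    nodes: list[KNode]
    adj: list[list[int]]           # successor ids in creation order
    s: int
    t: int
    k: int
    variant: str                   # "G" | "Gk"
    topo: list[int] = field(default_factory=list)   # Gk only
    loops: list[tuple[int, str]] = field(default_factory=list)  # G only: (split id, "star"/"plus")

    def node(self, i: int) -> KNode:
        return self.nodes[i]

    def succ(self, i: int) -> list[int]:
        return self.adj[i]

    @property
    def arcs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, out in enumerate(self.adj) for j in out]

    def character_nodes(self) -> list[int]:
        return [n.id for n in self.nodes if n.kind == CHARACTER]

    def to_dot(self) -> str:
        """GraphViz DOT text for inspection."""
        lines = ["digraph kgraph {", "  rankdir=LR;"]
        for n in self.nodes:
            if n.kind == CHARACTER:
                lines.append(f'  n{n.id} [label="{n.id}:{n.char}" shape=circle];')
            else:
                lines.append(f'  n{n.id} [label="{n.id}:{n.kind}" shape=box];')
        for i, j in self.arcs:
            lines.append(f"  n{i} -> n{j};")
        lines.append("}")
        return "\n".join(lines)


class _Builder:
    def __init__(self) -> None:
        self.nodes: list[KNode] = []
        self.adj: list[list[int]] = []

    def add(self, kind: str, char: Optional[str] = None) -> int:
        nid = len(self.nodes)
        self.nodes.append(KNode(nid, kind, char))
        self.adj.append([])
        return nid

    def arc(self, i: int, j: int) -> None:
        self.adj[i].append(j)

    def clone(self, frag: "_Frag") -> "_Frag":
        mapping = {old: self.add(self.nodes[old].kind, self.nodes[old].char)
                   for old in frag.members}
        for old in frag.members:
            for succ in self.adj[old]:
                if succ in mapping:
                    self.arc(mapping[old], mapping[succ])
        return _Frag(mapping[frag.entry], mapping[frag.exit],
                     [mapping[m] for m in frag.members])


@dataclass
class _Frag:
    entry: int
    exit: int
    members: list[int]


def build_graph(postfix: list[str], k: int, variant: str = "Gk") -> KGraph:
    """Stack construction of G or G^k from a postfix token sequence.

    Each operator case mirrors the node-based Thompson construction; in the
    acyclic variant, * and + operands are duplicated k-1 times behind split
    nodes so the operand can be traversed 0..k-1 (star) or 1..k-1 (plus)
    times, each repetition count along exactly one walk.
    """
    if variant not in ("G", "Gk"):
        raise ValueError(f"unknown variant {variant!r}")
    b = _Builder()
    stack: list[_Frag] = []
    loops: list[tuple[int, str]] = []

    def pop() -> _Frag:
        if not stack:
            raise PostfixError("stack underflow while building the graph")
        return stack.pop()

    for tok in postfix:
        if tok == CONCAT:
            ab, cd = pop(), pop()
            b.arc(cd.exit, ab.entry)
            stack.append(_Frag(cd.entry, ab.exit, cd.members + ab.members))
        elif tok == "|":
            ab, cd = pop(), pop()
            sp = b.add(SPLIT)
            jn = b.add(JOIN)
            b.arc(sp, ab.entry)
            b.arc(sp, cd.entry)
            b.arc(ab.exit, jn)
            b.arc(cd.exit, jn)
            stack.append(_Frag(sp, jn, ab.members + cd.members + [sp, jn]))
        elif tok in ("*", "+"):
            frag = pop()
            if variant == "G":
                sp = b.add(SPLIT)
                b.arc(sp, frag.entry)
                b.arc(frag.exit, sp)
                loops.append((sp, "star" if tok == "*" else "plus"))
                if tok == "*":
                    stack.append(_Frag(sp, sp, frag.members + [sp]))
                else:
                    stack.append(_Frag(frag.entry, sp, frag.members + [sp]))
            else:
                stack.append(_unroll(b, frag, k, tok))
        else:
            v = b.add(CHARACTER, tok)
            stack.append(_Frag(v, v, [v]))

    if len(stack) != 1:
        raise PostfixError(f"{len(stack)} fragments left after parsing")
    top = stack[0]
    s = b.add(ENTRY)
    t = b.add(EXIT)
    b.arc(s, top.entry)
    b.arc(top.exit, t)

    g = KGraph(nodes=b.nodes, adj=b.adj, s=s, t=t, k=k, variant=variant, loops=loops)
    if variant == "Gk":
        g.topo = topo_order(g)
    return g


def _unroll(b: _Builder, frag: _Frag, k: int, op: str) -> _Frag:
    """Acyclic replacement of a repeat subgraph (the original fragment serves
    as the first copy)."""
    if k == 1:
        # No complete k-mer can depend on symbols inside the repeat beyond
        # what a single (plus) or zero (star) traversal provides.
        if op == "+":
            return frag
        jn = b.add(JOIN)
        return _Frag(jn, jn, [jn])
    copies = [frag] + [b.clone(frag) for _ in range(k - 2)]
    lo = 1 if op == "*" else 2
    splits = {i: b.add(SPLIT) for i in range(lo, k)}
    jn = b.add(JOIN)
    for i in range(lo, k):
        b.arc(splits[i], copies[i - 1].entry)
    for i in range(1, k - 1):
        b.arc(copies[i - 1].exit, splits[i + 1])
    for i in range(lo, k):
        b.arc(splits[i], jn)
    b.arc(copies[k - 2].exit, jn)
    members = [m for c in copies for m in c.members] + list(splits.values()) + [jn]
    if op == "*":
        return _Frag(splits[1], jn, members)
    return _Frag(copies[0].entry, jn, members)


def topo_order(g: KGraph) -> list[int]:
    """Kahn topological order, ties broken by ascending node id; s is first
    and t last. Raises CycleError on a cycle (a construction bug for G^k)."""
    indeg = [0] * len(g.nodes)
    for _, j in g.arcs:
        indeg[j] += 1
    ready = [i for i in range(len(g.nodes)) if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for j in g.adj[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(ready, j)
    if len(order) != len(g.nodes):
        raise CycleError("graph contains a cycle; no topological order exists")
    return order


@dataclass(frozen=True)
class Walk:
    nodes: tuple[int, ...]
    word: str
    kmers: tuple[str, ...]


def enumerate_walks(g: KGraph, max_repeat: int = 1,
                    max_walks: int = 100_000) -> list[Walk]:
    """All (s,t)-walks, each with its spelled word and ordered k-mer list.

    For the cyclic variant G, each node may be visited at most
    ``max_repeat + 1`` times, which bounds every repeat subgraph to at most
    ``max_repeat`` traversals. G^k needs no bound (its walk set is finite) but
    ``max_walks`` still caps the output.
    """
    cap = 1 if g.variant == "Gk" else max_repeat + 1
    out: list[Walk] = []
    visits = [0] * len(g.nodes)
    path: list[int] = []
    chars: list[str] = []

    def dfs(v: int) -> None:
        visits[v] += 1
        path.append(v)
        node = g.node(v)
        if node.kind == CHARACTER:
            chars.append(node.char)
        if v == g.t:
            if len(out) >= max_walks:
                raise WalkBudgetExceeded(f"more than {max_walks} (s,t)-walks")
            word = "".join(chars)
            kmers = tuple(word[i:i + g.k] for i in range(len(word) - g.k + 1))
            out.append(Walk(tuple(path), word, kmers))
        else:
            for w in g.adj[v]:
                if visits[w] < cap:
                    dfs(w)
        if node.kind == CHARACTER:
            chars.pop()
        path.pop()
        visits[v] -= 1

    dfs(g.s)
    return out


@dataclass(frozen=True)
class ComplexityResult:
    v: tuple[int, ...]        # one k-mer count per character node, topo order
    c_k: int
    char_order: tuple[int, ...]  # character node ids in the same order


def kmer_complexity(g: KGraph) -> ComplexityResult:
    """k-mer complexity c_k of an acyclic k-graph.

    One sweep in topological order over a node-by-k count matrix: visiting a
    character node shifts its row right by one, sets column 0 to 1 (a fresh
    window starts here) and reports the last column (windows completing here)
    into v; every node then adds its row to each direct successor. v[i] equals
    the number of directed paths with exactly k character nodes ending at the
    i-th character node, and c_k is their sum.
    """
    if g.variant != "Gk":
        raise ValueError("k-mer complexity is defined on the acyclic variant")
    k = g.k
    m = [[0] * k for _ in g.nodes]
    v: list[int] = []
    order: list[int] = []
    for i in g.topo:
        row = m[i]
        if g.node(i).kind == CHARACTER:
            row = [1] + row[:-1]
            m[i] = row
            v.append(row[-1])
            order.append(i)
        for j in g.adj[i]:
            tgt = m[j]
            for c in range(k):
                tgt[c] += row[c]
    return ComplexityResult(v=tuple(v), c_k=sum(v), char_order=tuple(order))
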