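"""Independent oracles shared by the test modules.

These deliberately avoid the package's own conversion paths: core trees are
translated to Python ``re`` syntax for membership checks, PROSITE-like text
is translated directly (without the package parser) for cross-validation,
and path counting / longest-match oracles are brute force.
"""
from __future__ import annotations

import re
from collections import Counter

from seqrex import Alt, Cat, Lit, Plus, Star
from seqrex.alphabet import get_alphabet


def core_to_re(r) -> str:
    if isinstance(r, Lit):
        return re.escape(r.char)
    if isinstance(r, Cat):
        return core_to_re(r.left) + core_to_re(r.right)
    if isinstance(r, Alt):
        return f"(?:{core_to_re(r.left)}|{core_to_re(r.right)})"
    if isinstance(r, Star):
        return f"(?:{core_to_re(r.child)})*"
    if isinstance(r, Plus):
        return f"(?:{core_to_re(r.child)})+"
    raise TypeError(r)


def compiled(r) -> re.Pattern:
    return re.compile(core_to_re(r))


def prosite_to_re(raw: str, alphabet: str = "protein") -> re.Pattern:
    """Direct PROSITE-to-re translation, independent of the package parser."""
    ab = get_alphabet(alphabet)
    elements: list[str] = []
    i = 0
    text = raw.upper().replace("-", "")
    while i < len(text):
        c = text[i]
        if c == "[":
            j = text.index("]", i)
            elements.append(f"[{text[i + 1:j]}]")
            i = j + 1
        elif c == "{":
            j = text.index("}", i)
            keep = "".join(s for s in ab.symbols if s not in text[i + 1:j])
            elements.append(f"[{keep}]")
            i = j + 1
        elif c == "(":
            j = text.index(")", i)
            elements[-1] = f"(?:{elements[-1]}){{{text[i + 1:j]}}}"
            i = j + 1
        elif c in "X_.":
            elements.append(f"[{ab.symbols}]")
            i += 1
        else:
            elements.append(re.escape(c))
            i += 1
    return re.compile("".join(elements))


def longest_match_at(pattern: re.Pattern, text: str, i: int) -> int | None:
    """Longest j with fullmatch(text[i:j]); brute force from the right."""
    for j in range(len(text), i, -1):
        if pattern.fullmatch(text, i, j):
            return j
    return None


def all_longest_matches(pattern: re.Pattern, text: str) -> set[tuple[int, int]]:
    out = set()
    for i in range(len(text)):
        j = longest_match_at(pattern, text, i)
        if j is not None and j > i:
            out.add((i, j))
    return out


def count_k_paths(g) -> Counter:
    """Directed paths with exactly k character nodes, keyed by final node."""
    chars = set(g.character_nodes())
    ends: Counter = Counter()

    def dfs(v: int, c: int) -> None:
        if v in chars:
            c += 1
            if c == g.k:
                ends[v] += 1
                return
        for w in g.succ(v):
            dfs(w, c)

    for v0 in chars:
        dfs(v0, 0)
    return ends


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))
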