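"""Regex front-end: pattern dialects, core AST, and postfix conversion.

The core grammar over an alphabet Sigma has literals, concatenation,
union (``|``), Kleene star (``*``) and plus (``+``). User-facing dialects add
syntactic sugar that is expanded away at parse time:

* character classes ``[TC]`` become unions of their members,
* negated classes ``{GQ}`` (PROSITE-like dialect only) become unions over the
  complement of the listed residues,
* wildcards (``_``, ``.``, ``x``) become the union over the whole alphabet,
* bounded repeats ``E(n)`` / ``E(n,m)`` are macro-expanded into unions of
  concatenation chains of n..m copies of E,
* the PROSITE element separator ``-`` is discarded.

Two assumptions required by the downstream k-mer filter are checked by
:func:`validate_for_k`: no accepted word may be shorter than k, and no star or
plus operand may accept the empty word.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Union

from .alphabet import Alphabet, get_alphabet
from .errors import (
    AlphabetError,
    EmptyRepeatError,
    ExpansionLimitError,
    MinLengthError,
    PatternSyntaxError,
    PostfixError,
)

CONCAT = "∘"  # the explicit concatenation operator in postfix output
WILDCARDS = frozenset("_.X")

DEFAULT_EXPANSION_CAP = 10_000


# ---------------------------------------------------------------------------
# Core AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lit:
    char: str

    def __str__(self) -> str:
        return self.char


@dataclass(frozen=True)
class Cat:
    left: "CoreRegex"
    right: "CoreRegex"

    def __str__(self) -> str:
        return f"{self.left}{self.right}"


@dataclass(frozen=True)
class Alt:
    left: "CoreRegex"
    right: "CoreRegex"

    def __str__(self) -> str:
        return f"({self.left}|{self.right})"


@dataclass(frozen=True)
class Star:
    child: "CoreRegex"

    def __str__(self) -> str:
        return f"({self.child})*"


@dataclass(frozen=True)
class Plus:
    child: "CoreRegex"

    def __str__(self) -> str:
        return f"({self.child})+"


CoreRegex = Union[Lit, Cat, Alt, Star, Plus]


@dataclass(frozen=True)
class PatternText:
    """A raw user pattern together with its dialect and alphabet."""

    raw: str
    dialect: str = "core"          # "core" | "prosite_like"
    alphabet: str = "dna"


def tree_size(r: CoreRegex) -> int:
    if isinstance(r, Lit):
        return 1
    if isinstance(r, (Cat, Alt)):
        return 1 + tree_size(r.left) + tree_size(r.right)
    return 1 + tree_size(r.child)


def minlen(r: CoreRegex) -> int:
    """Length of the shortest word in L(r)."""
    if isinstance(r, Lit):
        return 1
    if isinstance(r, Cat):
        return minlen(r.left) + minlen(r.right)
    if isinstance(r, Alt):
        return min(minlen(r.left), minlen(r.right))
    if isinstance(r, Star):
        return 0
    if isinstance(r, Plus):
        return minlen(r.child)
    raise TypeError(f"not a CoreRegex node: {r!r}")


def literal_word(word: str) -> CoreRegex:
    """Concatenation chain for a plain word."""
    if not word:
        raise PatternSyntaxError("empty word has no core representation")
    node: CoreRegex = Lit(word[0])
    for c in word[1:]:
        node = Cat(node, Lit(c))
    return node


def _union_of(chars: str) -> CoreRegex:
    node: CoreRegex = Lit(chars[0])
    for c in chars[1:]:
        node = Alt(node, Lit(c))
    return node


def _concat_copies(r: CoreRegex, n: int) -> CoreRegex:
    node = r
    for _ in range(n - 1):
        node = Cat(node, r)
    return node


# ---------------------------------------------------------------------------
# Dialect parser
# ---------------------------------------------------------------------------

class _Parser:
    """Recursive-descent parser shared by the two dialects.

    Operator precedence follows standard regex convention: postfix * / + /
    bounded repeats bind tightest, then implicit concatenation, then |.
    Parentheses group, except that ``(digits[,digits])`` directly after an
    element is a bounded repeat (the PROSITE reading; unambiguous because
    digits are not alphabet symbols).
    """

    def __init__(self, text: str, dialect: str, alphabet: Alphabet, cap: int):
        self.text = text
        self.pos = 0
        self.dialect = dialect
        self.alphabet = alphabet
        self.cap = cap

    def error(self, msg: str) -> PatternSyntaxError:
        return PatternSyntaxError(f"{msg} (at position {self.pos} of {self.text!r})")

    def peek(self) -> str | None:
        return self.text[self.pos] if self.pos < len(self.text) else None

    def take(self) -> str:
        c = self.text[self.pos]
        self.pos += 1
        return c

    # grammar ---------------------------------------------------------------

    def parse(self) -> CoreRegex:
        node = self.alt()
        if self.peek() is not None:
            raise self.error(f"unexpected {self.peek()!r}")
        return node

    def alt(self) -> CoreRegex:
        node = self.seq()
        while self.peek() == "|":
            self.take()
            node = Alt(node, self.seq())
        return node

    def seq(self) -> CoreRegex:
        parts = []
        while True:
            c = self.peek()
            if c is None or c in ")|":
                break
            parts.append(self.rep())
        if not parts:
            raise self.error("empty subexpression")
        node = parts[0]
        for p in parts[1:]:
            node = Cat(node, p)
        return node

    def rep(self) -> CoreRegex:
        node = self.atom()
        while True:
            c = self.peek()
            if c == "*":
                self.take()
                node = Star(node)
            elif c == "+":
                self.take()
                node = Plus(node)
            elif c == "(" and self._looks_like_bounds():
                node = self._bounded_repeat(node)
            else:
                return node

    def _looks_like_bounds(self) -> bool:
        j = self.pos + 1
        seen_digit = False
        while j < len(self.text) and (self.text[j].isdigit() or self.text[j] == ","):
            seen_digit = seen_digit or self.text[j].isdigit()
            j += 1
        return seen_digit and j < len(self.text) and self.text[j] == ")"

    def _bounded_repeat(self, node: CoreRegex) -> CoreRegex:
        self.take()  # "("
        digits = ""
        while self.peek() is not None and self.peek() != ")":
            digits += self.take()
        if self.peek() is None:
            raise self.error("unterminated repeat bound")
        self.take()  # ")"
        parts = digits.split(",")
        try:
            lo = int(parts[0])
            hi = int(parts[1]) if len(parts) > 1 else lo
        except (ValueError, IndexError):
            raise self.error(f"malformed repeat bound ({digits!r})")
        if lo < 1:
            raise self.error("repeat lower bound must be >= 1 "
                             "(the core grammar has no empty word)")
        if lo > hi:
            raise self.error(f"repeat bound with n > m ({lo},{hi})")
        base = tree_size(node)
        projected = base * (hi * (hi + 1) - lo * (lo - 1)) // 2 + 2 * (hi - lo + 1)
        if projected > self.cap:
            raise ExpansionLimitError(
                f"repeat ({lo},{hi}) would expand to about {projected} nodes "
                f"(cap {self.cap})")
        out = _concat_copies(node, lo)
        for n in range(lo + 1, hi + 1):
            out = Alt(out, _concat_copies(node, n))
        return out

    def atom(self) -> CoreRegex:
        c = self.peek()
        if c is None:
            raise self.error("unexpected end of pattern")
        if c == "(":
            self.take()
            node = self.alt()
            if self.peek() != ")":
                raise self.error("unbalanced parenthesis")
            self.take()
            return node
        if c == "[":
            return self._char_class(negated=False)
        if c == "{":
            if self.dialect != "prosite_like":
                raise self.error("negated classes {..} are only accepted in the "
                                 "PROSITE-like dialect")
            return self._char_class(negated=True)
        if c in WILDCARDS:
            self.take()
            return _union_of(self.alphabet.symbols)
        self.take()
        if c not in self.alphabet:
            raise AlphabetError(
                f"symbol {c!r} at position {self.pos - 1} is not in the "
                f"{self.alphabet.name} alphabet")
        return Lit(c)

    def _char_class(self, negated: bool) -> CoreRegex:
        close = "}" if negated else "]"
        self.take()
        members = ""
        while self.peek() is not None and self.peek() != close:
            c = self.take()
            if c not in self.alphabet:
                raise AlphabetError(f"class member {c!r} is not in the "
                                    f"{self.alphabet.name} alphabet")
            if c not in members:
                members += c
        if self.peek() != close:
            raise self.error("unbalanced class bracket")
        self.take()
        if not members:
            raise self.error("empty character class")
        if negated:
            members = "".join(c for c in self.alphabet.symbols if c not in members)
            if not members:
                raise self.error("negated class excludes the whole alphabet")
        return _union_of(members)


def expand_pattern(pattern: PatternText | str,
                   dialect: str = "core",
                   alphabet: str = "dna",
                   expansion_cap: int = DEFAULT_EXPANSION_CAP) -> CoreRegex:
    """Parse a pattern and expand all syntactic sugar into the core grammar.

    The returned tree contains only literals, concatenation, union, star and
    plus, and denotes exactly the language of the input pattern.
    """
    if isinstance(pattern, PatternText):
        raw, dialect, alphabet = pattern.raw, pattern.dialect, pattern.alphabet
    else:
        raw = pattern
    if not raw:
        raise PatternSyntaxError("empty pattern")
    if dialect not in ("core", "prosite_like"):
        raise PatternSyntaxError(f"unknown dialect {dialect!r}")
    ab = get_alphabet(alphabet)
    text = raw.upper().replace("-", "")
    # PROSITE records terminate patterns with "." and may carry anchors; the
    # trailing period would otherwise read as a wildcard.
    if dialect == "prosite_like":
        text = text.removesuffix(".")
        if "<" in text or ">" in text:
            raise PatternSyntaxError("N/C-terminus anchors (< >) are not supported")
    if not text:
        raise PatternSyntaxError("pattern contains no elements")
    return _Parser(text, dialect, ab, expansion_cap).parse()


# ---------------------------------------------------------------------------
# Validation, postfix
# ---------------------------------------------------------------------------

def _repeat_operands(r: CoreRegex) -> Iterator[CoreRegex]:
    if isinstance(r, (Star, Plus)):
        yield r.child
        yield from _repeat_operands(r.child)
    elif isinstance(r, (Cat, Alt)):
        yield from _repeat_operands(r.left)
        yield from _repeat_operands(r.right)


def validate_for_k(r: CoreRegex, k: int) -> CoreRegex:
    """Check the two filter preconditions; return ``r`` unchanged if both hold."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for child in _repeat_operands(r):
        if minlen(child) == 0:
            raise EmptyRepeatError(
                "a * or + operand accepts the empty word; rewrite the pattern "
                "so repeated subexpressions are non-empty")
    m = minlen(r)
    if m < k:
        raise MinLengthError(
            f"the pattern accepts words of length {m} < k={k}; lower k or use "
            "a plain linear scan (no index acceleration is possible)")
    return r


def to_postfix(r: CoreRegex) -> list[str]:
    """Post-order token sequence over Sigma and {CONCAT, |, *, +}."""
    out: list[str] = []

    def walk(node: CoreRegex) -> None:
        if isinstance(node, Lit):
            out.append(node.char)
        elif isinstance(node, Cat):
            walk(node.left)
            walk(node.right)
            out.append(CONCAT)
        elif isinstance(node, Alt):
            walk(node.left)
            walk(node.right)
            out.append("|")
        elif isinstance(node, Star):
            walk(node.child)
            out.append("*")
        elif isinstance(node, Plus):
            walk(node.child)
            out.append("+")
        else:
            raise TypeError(f"not a CoreRegex node: {node!r}")

    walk(r)
    return out


def postfix_to_tree(tokens: list[str]) -> CoreRegex:
    """Rebuild an AST by stack evaluation; raises PostfixError if malformed."""
    stack: list[CoreRegex] = []
    for tok in tokens:
        try:
            if tok == CONCAT:
                b, a = stack.pop(), stack.pop()
                stack.append(Cat(a, b))
            elif tok == "|":
                b, a = stack.pop(), stack.pop()
                stack.append(Alt(a, b))
            elif tok == "*":
                stack.append(Star(stack.pop()))
            elif tok == "+":
                stack.append(Plus(stack.pop()))
            else:
                stack.append(Lit(tok))
        except IndexError:
            raise PostfixError(f"stack underflow at token {tok!r}")
    if len(stack) != 1:
        raise PostfixError(f"{len(stack)} items left on the stack")
    return stack[0]


# ---------------------------------------------------------------------------
# Language utilities (bounded enumeration, sampling, random trees)
# ---------------------------------------------------------------------------

def enumerate_language(r: CoreRegex, max_len: int) -> set[str]:
    """All words of L(r) of length <= max_len (brute-force; small patterns only)."""
    if isinstance(r, Lit):
        return {r.char} if max_len >= 1 else set()
    if isinstance(r, Cat):
        left = enumerate_language(r.left, max_len)
        right = enumerate_language(r.right, max_len)
        return {a + b for a in left for b in right if len(a) + len(b) <= max_len}
    if isinstance(r, Alt):
        return enumerate_language(r.left, max_len) | enumerate_language(r.right, max_len)
    if isinstance(r, Star):
        words = {""}
        unit = enumerate_language(r.child, max_len)
        frontier = {""}
        while frontier:
            nxt = {a + b for a in frontier for b in unit if len(a) + len(b) <= max_len}
            frontier = nxt - words
            words |= nxt
        return words
    if isinstance(r, Plus):
        return enumerate_language(Cat(r.child, Star(r.child)), max_len)
    raise TypeError(f"not a CoreRegex node: {r!r}")


def sample_word(r: CoreRegex, rng, rep_p: float = 0.5, rep_cap: int = 8) -> str:
    """Draw one word of L(r).

    Unions pick a branch uniformly; star/plus repetition counts are geometric
    with continuation probability ``rep_p``, capped at ``rep_cap``; each
    repetition re-samples the operand independently.
    """
    if isinstance(r, Lit):
        return r.char
    if isinstance(r, Cat):
        return sample_word(r.left, rng, rep_p, rep_cap) + sample_word(r.right, rng, rep_p, rep_cap)
    if isinstance(r, Alt):
        branch = r.left if rng.random() < 0.5 else r.right
        return sample_word(branch, rng, rep_p, rep_cap)
    if isinstance(r, (Star, Plus)):
        n = 1 if isinstance(r, Plus) else 0
        while n < rep_cap and rng.random() < rep_p:
            n += 1
        return "".join(sample_word(r.child, rng, rep_p, rep_cap) for _ in range(n))
    raise TypeError(f"not a CoreRegex node: {r!r}")


def random_regex(rng, max_depth: int = 4, alphabet: str = "dna",
                 allow_repeat: bool = True) -> CoreRegex:
    """Random core tree for property tests; repeat operands never accept epsilon."""
    ab = get_alphabet(alphabet)

    def build(depth: int) -> CoreRegex:
        if depth <= 0:
            return Lit(ab.symbols[int(rng.integers(ab.size))])
        roll = rng.random()
        if roll < 0.35:
            return Lit(ab.symbols[int(rng.integers(ab.size))])
        if roll < 0.65:
            return Cat(build(depth - 1), build(depth - 1))
        if roll < 0.85 or not allow_repeat:
            return Alt(build(depth - 1), build(depth - 1))
        for _ in range(20):
            child = build(depth - 1)
            if minlen(child) >= 1:
                return (Star if rng.random() < 0.5 else Plus)(child)
        return Lit(ab.symbols[int(rng.integers(ab.size))])

    return build(max_depth)
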