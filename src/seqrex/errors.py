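"""Exception hierarchy for seqrex."""


class SeqrexError(Exception):
    """Base class for all seqrex errors."""


class PatternSyntaxError(SeqrexError):
    """Malformed pattern text (unbalanced brackets, empty class, bad repeat bound...)."""


class AlphabetError(SeqrexError):
    """A symbol outside the declared alphabet (or an illegal query k-mer)."""


class ExpansionLimitError(SeqrexError):
    """Bounded-repeat macro expansion would exceed the configured node cap."""


class MinLengthError(SeqrexError):
    """L(R) contains words shorter than k.

    The k-mer filter requires every accepted word to carry at least one
    complete k-mer. Lower k, or fall back to a plain linear scan.
    """


class EmptyRepeatError(SeqrexError):
    """A * or + operand accepts the empty word, which the unrolling forbids."""


class PostfixError(SeqrexError):
    """Postfix token sequence is not stack-well-formed."""


class CycleError(SeqrexError):
    """A cycle was found where the graph must be acyclic (construction bug)."""


class WalkBudgetExceeded(SeqrexError):
    """More (s,t)-walks exist than the caller's enumeration budget allows."""


class IndexFormatError(SeqrexError):
    """Corrupt, truncated, or version-mismatched index file."""


class IndexMismatchError(SeqrexError):
    """Index parameters (k, bin count, alphabet) disagree with the query."""
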