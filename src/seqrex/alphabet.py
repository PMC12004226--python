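"""Sequence alphabets: symbol sets, ambiguity codes, and k-mer packing.

Two alphabets are supported: the four-letter nucleotide alphabet and the
twenty-letter amino-acid alphabet. k-mers over either are packed into a
single unsigned 64-bit integer (2 bits per nucleotide, 5 bits per residue)
for hashing and exact-set storage, which bounds k at 32 (DNA) / 12 (protein).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlphabetError

DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Alphabet:
    name: str
    symbols: str          # unambiguous symbols, index = packed code
    ambiguous: str        # legal in sequence records, skipped at indexing
    bits: int             # bits per packed symbol

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def max_k(self) -> int:
        return 64 // self.bits

    def __contains__(self, c: str) -> bool:
        return c in self.symbols

    def code(self, c: str) -> int:
        i = self.symbols.find(c)
        if i < 0:
            raise AlphabetError(f"symbol {c!r} is not in the {self.name} alphabet")
        return i

    def code_table(self) -> np.ndarray:
        """Byte -> code lookup table; 255 marks non-alphabet bytes."""
        table = np.full(256, 255, dtype=np.uint8)
        for i, c in enumerate(self.symbols):
            table[ord(c)] = i
            table[ord(c.lower())] = i
        return table

    def pack(self, kmer: str) -> int:
        """Pack an unambiguous k-mer into an integer (first symbol = high bits)."""
        x = 0
        for c in kmer:
            x = (x << self.bits) | self.code(c)
        return x


DNA = Alphabet(name="dna", symbols="ACGT", ambiguous="NRYSWKMBDHV", bits=2)
PROTEIN = Alphabet(
    name="protein",
    symbols="ACDEFGHIKLMNPQRSTVWY",
    ambiguous="BJOUXZ",
    bits=5,
)

ALPHABETS = {"dna": DNA, "protein": PROTEIN}


def get_alphabet(name: str) -> Alphabet:
    try:
        return ALPHABETS[name]
    except KeyError:
        raise AlphabetError(f"unknown alphabet {name!r} (expected 'dna' or 'protein')")


def reverse_complement(seq: str) -> str:
    try:
        return "".join(DNA_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as e:
        raise AlphabetError(f"cannot reverse-complement symbol {e.args[0]!r}")


def pack_kmers(seq: str, k: int, alphabet: Alphabet) -> np.ndarray:
    """All packed k-mers of ``seq`` whose windows are free of ambiguity codes.

    Vectorized; windows never span record boundaries because the caller hands
    in one record at a time. Returns a uint64 array (possibly empty).
    """
    if k > alphabet.max_k:
        raise AlphabetError(f"k={k} exceeds the packable maximum {alphabet.max_k} "
                            f"for the {alphabet.name} alphabet")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes = alphabet.code_table()[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = (codes == 255).astype(np.int64)
    kmers = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        kmers = (kmers << np.uint64(alphabet.bits)) | codes[j:j + n - k + 1].astype(np.uint64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    window_bad = (cs[k:] - cs[:-k]) > 0
    return kmers[~window_bad]
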