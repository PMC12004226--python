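"""Interleaved Bloom filter over binned FASTA data, plus exact test oracles.

The index holds one Bloom filter per user bin, stored interleaved: bit row r
is a u-bit slice containing position r of every bin's filter, so querying a
k-mer touches only h rows and yields a u-bit *binning bitvector* in one pass
(bit j set = bin j possibly contains the k-mer; never a false negative).

k-mers are packed into 64-bit integers (2 bits per nucleotide, 5 per residue)
and double-hashed with a seeded splitmix64 pair: position_i = (h1 + i*h2)
mod bits_per_bin. Windows containing ambiguity codes (N, X, ...) are skipped
at build time; k-mers never span record boundaries, but they do span line
breaks within a record because lines are concatenated on parsing.
"""
from __future__ import annotations

import io
import json
import math
import struct
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import Alphabet, get_alphabet, pack_kmers
from .errors import IndexFormatError, IndexMismatchError

_MAGIC = b"SEQREXIBF"
_VERSION = 1
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


# ---------------------------------------------------------------------------
# Binning bitvector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bitvector:
    """A u-bit membership vector; bit j (printed leftmost-first) = bin j."""

    u: int
    value: int = 0

    @classmethod
    def zeros(cls, u: int) -> "Bitvector":
        return cls(u, 0)

    @classmethod
    def ones(cls, u: int) -> "Bitvector":
        return cls(u, (1 << u) - 1)

    @classmethod
    def from_indices(cls, u: int, indices: Iterable[int]) -> "Bitvector":
        v = 0
        for j in indices:
            v |= 1 << int(j)
        return cls(u, v)

    @classmethod
    def from01(cls, bits: str) -> "Bitvector":
        """Parse the figure notation, e.g. '010' = only the second bin."""
        v = 0
        for j, c in enumerate(bits):
            if c == "1":
                v |= 1 << j
        return cls(len(bits), v)

    @classmethod
    def from_bool(cls, row: np.ndarray) -> "Bitvector":
        return cls.from_indices(len(row), np.flatnonzero(row))

    def __and__(self, other: "Bitvector") -> "Bitvector":
        return Bitvector(self.u, self.value & other.value)

    def __or__(self, other: "Bitvector") -> "Bitvector":
        return Bitvector(self.u, self.value | other.value)

    def get(self, j: int) -> bool:
        return bool(self.value >> j & 1)

    def count(self) -> int:
        return self.value.bit_count()

    def indices(self) -> list[int]:
        return [j for j in range(self.u) if self.value >> j & 1]

    def any(self) -> bool:
        return self.value != 0

    def __str__(self) -> str:
        return "".join("1" if self.value >> j & 1 else "0" for j in range(self.u))


# ---------------------------------------------------------------------------
# Hashing
# ---------------------------------------------------------------------------

def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer, vectorized over uint64."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK64
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK64
    return x ^ (x >> np.uint64(31))


def hash_positions(kmers: np.ndarray, h: int, m: int, seed: int) -> np.ndarray:
    """(n, h) array of bit-row positions via double hashing."""
    kmers = np.asarray(kmers, dtype=np.uint64)
    h1 = _mix64(kmers ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    h2 = _mix64(kmers ^ np.uint64((seed * 0x5851F42D4C957F2D + 1) & 0xFFFFFFFFFFFFFFFF))
    h2 = h2 | np.uint64(1)
    out = np.empty((len(kmers), h), dtype=np.int64)
    for i in range(h):
        out[:, i] = ((h1 + np.uint64(i) * h2) % np.uint64(m)).astype(np.int64)
    return out


def size_from_fpr(n_max_kmers_per_bin: int, p: float, h: int) -> int:
    """Smallest per-bin filter size m with (1 - e^(-h*n/m))^h <= p."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"false-positive rate must be in (0, 1), got {p}")
    if n_max_kmers_per_bin < 1:
        raise ValueError("need at least one k-mer per bin")
    n = n_max_kmers_per_bin

    def fpr(m: int) -> float:
        return (1.0 - math.exp(-h * n / m)) ** h

    m = max(1, math.ceil(-h * n / math.log(1.0 - p ** (1.0 / h))))
    while fpr(m) > p:
        m += 1
    while m > 1 and fpr(m - 1) <= p:
        m -= 1
    return m


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexConfig:
    u: int
    k: int
    h: int = 3
    bits_per_bin: int | None = None   # sized from target_fpr when None
    target_fpr: float = 0.05
    alphabet: str = "dna"
    hash_seed: int = 0x5EC5  # deterministic default

    def __post_init__(self) -> None:
        if self.u < 1 or self.k < 1 or self.h < 1:
            raise ValueError("u, k and h must all be >= 1")
        if self.bits_per_bin is not None and self.bits_per_bin < 1:
            raise ValueError("bits_per_bin must be >= 1")
        if not 0.0 < self.target_fpr < 1.0:
            raise ValueError("target_fpr must be in (0, 1)")
        get_alphabet(self.alphabet)


def _read_bin_records(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bin file not found: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return records


# ---------------------------------------------------------------------------
# Interleaved Bloom filter
# ---------------------------------------------------------------------------

class InterleavedBloomFilter:
    """u interleaved Bloom filters with a shared row layout.

    ``bits`` is a (bits_per_bin, u) boolean matrix: row r is the interleaved
    u-bit slice of position r across all bins.
    """

    def __init__(self, config: IndexConfig, bin_names: Sequence[str],
                 bin_paths: Sequence[str] | None = None):
        if config.bits_per_bin is None:
            raise ValueError("config.bits_per_bin must be resolved before construction")
        if len(bin_names) != config.u:
            raise ValueError("one name per bin required")
        self.config = config
        self.bin_names = list(bin_names)
        self.bin_paths = list(bin_paths) if bin_paths is not None else list(bin_names)
        self.bits = np.zeros((config.bits_per_bin, config.u), dtype=bool)
        self.per_bin_kmer_counts = np.zeros(config.u, dtype=np.int64)

    # -- basic properties ---------------------------------------------------

    @property
    def u(self) -> int:
        return self.config.u

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def alphabet(self) -> Alphabet:
        return get_alphabet(self.config.alphabet)

    # -- construction -------------------------------------------------------

    def insert_packed(self, bin_index: int, kmers: np.ndarray) -> None:
        if len(kmers) == 0:
            return
        pos = hash_positions(kmers, self.config.h, self.config.bits_per_bin,
                             self.config.hash_seed)
        self.bits[pos.ravel(), bin_index] = True
        self.per_bin_kmer_counts[bin_index] += len(kmers)

    # -- queries ------------------------------------------------------------

    def _pack_query(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise IndexMismatchError(
                f"query length {len(kmer)} != index k = {self.k}")
        return self.alphabet.pack(kmer.upper())

    def query_kmer(self, kmer: str) -> Bitvector:
        x = self._pack_query(kmer)
        pos = hash_positions(np.array([x], dtype=np.uint64), self.config.h,
                             self.config.bits_per_bin, self.config.hash_seed)[0]
        row = self.bits[pos].all(axis=0)
        return Bitvector.from_bool(row)

    def query_packed_many(self, kmers: np.ndarray) -> np.ndarray:
        """(n, u) boolean membership matrix for packed k-mers (batch path)."""
        pos = hash_positions(kmers, self.config.h, self.config.bits_per_bin,
                             self.config.hash_seed)
        return self.bits[pos].all(axis=1)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        header = {
            "u": self.config.u, "k": self.config.k, "h": self.config.h,
            "bits_per_bin": self.config.bits_per_bin,
            "target_fpr": self.config.target_fpr,
            "alphabet": self.config.alphabet,
            "hash_seed": self.config.hash_seed,
            "bin_names": self.bin_names,
            "bin_paths": self.bin_paths,
            "per_bin_kmer_counts": self.per_bin_kmer_counts.tolist(),
        }
        payload = json.dumps(header, sort_keys=True).encode()
        packed = np.packbits(self.bits, axis=None)
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<HQ", _VERSION, len(payload)))
            fh.write(payload)
            fh.write(packed.tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "InterleavedBloomFilter":
        with open(path, "rb") as fh:
            data = fh.read()
        buf = io.BytesIO(data)
        if buf.read(len(_MAGIC)) != _MAGIC:
            raise IndexFormatError(f"{path}: not a seqrex index file")
        head = buf.read(10)
        if len(head) < 10:
            raise IndexFormatError(f"{path}: truncated header")
        version, hlen = struct.unpack("<HQ", head)
        if version != _VERSION:
            raise IndexFormatError(f"{path}: unsupported index version {version}")
        payload = buf.read(hlen)
        if len(payload) < hlen:
            raise IndexFormatError(f"{path}: truncated header")
        header = json.loads(payload.decode())
        cfg = IndexConfig(u=header["u"], k=header["k"], h=header["h"],
                          bits_per_bin=header["bits_per_bin"],
                          target_fpr=header["target_fpr"],
                          alphabet=header["alphabet"],
                          hash_seed=header["hash_seed"])
        idx = cls(cfg, header["bin_names"], header["bin_paths"])
        nbits = cfg.bits_per_bin * cfg.u
        raw = buf.read()
        if len(raw) < (nbits + 7) // 8:
            raise IndexFormatError(f"{path}: truncated bit matrix")
        flat = np.unpackbits(np.frombuffer(raw, dtype=np.uint8), count=nbits)
        idx.bits = flat.reshape(cfg.bits_per_bin, cfg.u).astype(bool)
        idx.per_bin_kmer_counts = np.array(header["per_bin_kmer_counts"], dtype=np.int64)
        return idx


def build_index(bin_paths: Sequence[str | Path],
                cfg: IndexConfig) -> InterleavedBloomFilter:
    """Build an IBF over one FASTA file per bin (bin order = path order).

    Every length-k window of every record that is free of ambiguity codes is
    inserted for its bin; if ``cfg.bits_per_bin`` is None, the filter is sized
    from ``cfg.target_fpr`` for the fullest bin.
    """
    if not bin_paths:
        raise ValueError("empty bin list")
    if len(bin_paths) != cfg.u:
        raise IndexMismatchError(f"{len(bin_paths)} bin files but cfg.u = {cfg.u}")
    ab = get_alphabet(cfg.alphabet)
    per_bin: list[np.ndarray] = []
    for path in bin_paths:
        arrays = []
        for rid, seq in _read_bin_records(path):
            kmers = pack_kmers(seq, cfg.k, ab)
            if len(seq) >= cfg.k and len(kmers) < len(seq) - cfg.k + 1:
                warnings.warn(f"{path}:{rid}: windows containing ambiguity "
                              "codes were skipped")
            arrays.append(kmers)
        per_bin.append(np.concatenate(arrays) if arrays
                       else np.empty(0, dtype=np.uint64))
    if cfg.bits_per_bin is None:
        n_max = max(1, max(len(a) for a in per_bin))
        cfg = replace(cfg, bits_per_bin=size_from_fpr(n_max, cfg.target_fpr, cfg.h))
    names = [Path(p).stem for p in bin_paths]
    idx = InterleavedBloomFilter(cfg, names, [str(p) for p in bin_paths])
    for j, kmers in enumerate(per_bin):
        idx.insert_packed(j, kmers)
    return idx


# ---------------------------------------------------------------------------
# Exact oracles
# ---------------------------------------------------------------------------

class ExactKmerIndex:
    """Per-bin exact k-mer sets; the p -> 0 limit of the Bloom index.

    Same query interface as the IBF but with zero false positives, which makes
    it the reference oracle in tests and the backend for exact filtering on
    small databases.
    """

    def __init__(self, k: int, bin_names: Sequence[str], alphabet: str = "dna",
                 bin_paths: Sequence[str] | None = None):
        self.k = k
        self.bin_names = list(bin_names)
        self.bin_paths = list(bin_paths) if bin_paths is not None else list(bin_names)
        self.config_alphabet = alphabet
        self.sets: list[set[int]] = [set() for _ in bin_names]
        self.per_bin_kmer_counts = np.zeros(len(bin_names), dtype=np.int64)

    @property
    def u(self) -> int:
        return len(self.sets)

    @property
    def alphabet(self) -> Alphabet:
        return get_alphabet(self.config_alphabet)

    @classmethod
    def from_bins(cls, bin_paths: Sequence[str | Path], k: int,
                  alphabet: str = "dna") -> "ExactKmerIndex":
        if not bin_paths:
            raise ValueError("empty bin list")
        names = [Path(p).stem for p in bin_paths]
        idx = cls(k, names, alphabet, [str(p) for p in bin_paths])
        ab = idx.alphabet
        for j, path in enumerate(bin_paths):
            for _, seq in _read_bin_records(path):
                kmers = pack_kmers(seq, k, ab)
                idx.sets[j].update(kmers.tolist())
                idx.per_bin_kmer_counts[j] += len(kmers)
        return idx

    @classmethod
    def from_sequences(cls, bins: Sequence[str], k: int,
                       alphabet: str = "dna") -> "ExactKmerIndex":
        """Convenience constructor: one in-memory sequence per bin."""
        names = [f"bin{j + 1}" for j in range(len(bins))]
        idx = cls(k, names, alphabet)
        ab = idx.alphabet
        for j, seq in enumerate(bins):
            kmers = pack_kmers(seq.upper(), k, ab)
            idx.sets[j].update(kmers.tolist())
            idx.per_bin_kmer_counts[j] += len(kmers)
        return idx

    def query_kmer(self, kmer: str) -> Bitvector:
        if len(kmer) != self.k:
            raise IndexMismatchError(f"query length {len(kmer)} != index k = {self.k}")
        x = self.alphabet.pack(kmer.upper())
        return Bitvector.from_indices(
            self.u, (j for j, s in enumerate(self.sets) if x in s))


class MappingIndex:
    """A hand-specified k-mer -> bitvector table (worked-example index)."""

    def __init__(self, k: int, u: int, table: dict[str, str | Bitvector],
                 alphabet: str = "dna"):
        self.k = k
        self.u = u
        self.config_alphabet = alphabet
        self.bin_names = [f"bin{j + 1}" for j in range(u)]
        self.table = {km: (bv if isinstance(bv, Bitvector) else Bitvector.from01(bv))
                      for km, bv in table.items()}
        for km in self.table:
            if len(km) != k:
                raise IndexMismatchError(f"table k-mer {km!r} has length != {k}")

    @property
    def alphabet(self) -> Alphabet:
        return get_alphabet(self.config_alphabet)

    def query_kmer(self, kmer: str) -> Bitvector:
        if len(kmer) != self.k:
            raise IndexMismatchError(f"query length {len(kmer)} != index k = {self.k}")
        return self.table.get(kmer.upper(), Bitvector.zeros(self.u))
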