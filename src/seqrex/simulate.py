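"""Seeded synthetic corpora with planted regex instances.

The generator emulates a randomized nucleotide search experiment at desk
scale: a random i.i.d. text split into 2^b single-record bins, with a small
number of randomly drawn instances of known patterns written in at random
non-overlapping offsets — optionally positioned so the occurrence crosses a
FASTA line break, the classic failure mode of line-oriented scanners. A
truth table accompanies the corpus so that search results can be checked for
completeness.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import get_alphabet
from .errors import SeqrexError
from .fastaio import write_fasta
from .regexes import expand_pattern, sample_word, validate_for_k

DEFAULT_LINE_WIDTH = 70


@dataclass(frozen=True)
class PlantSpec:
    """One pattern to plant: how many instances, and whether one of them must
    span a line break (instance 0 stays within a line, instance 1 crosses
    one, further instances are unconstrained)."""

    pattern: str
    n_instances: int
    span_linebreak: bool = True
    dialect: str = "core"


@dataclass(frozen=True)
class SimSpec:
    n_bins: int = 64
    bin_chars: int = 65536
    alphabet: str = "dna"
    k: int = 13
    plants: tuple[PlantSpec, ...] = ()
    line_width: int = DEFAULT_LINE_WIDTH
    seed: int = 0


@dataclass(frozen=True)
class TruthRecord:
    bin_index: int
    record_id: str
    start: int
    end: int
    planted_word: str
    source_pattern: str


@dataclass
class SimResult:
    bin_paths: list[Path]
    truth_path: Path
    truth: list[TruthRecord]


def default_nucleotide_spec(seed: int = 0, n_bins: int = 64,
                            bin_chars: int = 65536, k: int = 13) -> SimSpec:
    """The package's standard nucleotide experiment at desk scale.

    Five regexes with minimum length >= k: four are planted twice each (one
    instance within a line, one across a line break) in random bins; the
    fifth is never planted, exercising the no-hit fast path.
    """
    plants = (
        PlantSpec("[TC]AAT[TC][AT]CCGATGA", 2),
        PlantSpec("ACGGTA(T)*AACTGCA", 2),
        PlantSpec("GAT(CA)+TTACGGAT", 2),
        PlantSpec("TGC[AG]CT[TG]ACCA[TC]GG", 2),
        PlantSpec("TTGACCAGTCGATCA", 0),
    )
    return SimSpec(n_bins=n_bins, bin_chars=bin_chars, k=k, plants=plants,
                   seed=seed)


def _record_id(j: int, digits: int) -> str:
    return f"seq_{j:0{digits}d}"


def simulate_corpus(spec: SimSpec, out_dir: str | Path) -> SimResult:
    """Generate bin FASTA files and a truth TSV; byte-deterministic per seed."""
    if spec.n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if spec.bin_chars < spec.k:
        raise ValueError("bin_chars must be >= k")
    ab = get_alphabet(spec.alphabet)
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    symbols = np.frombuffer(ab.symbols.encode(), dtype=np.uint8)
    texts = [symbols[rng.integers(0, ab.size, spec.bin_chars)].copy()
             for _ in range(spec.n_bins)]
    used: list[list[tuple[int, int]]] = [[] for _ in range(spec.n_bins)]
    digits = max(3, len(str(spec.n_bins - 1)))
    truth: list[TruthRecord] = []

    for plant in spec.plants:
        tree = expand_pattern(plant.pattern, dialect=plant.dialect,
                              alphabet=spec.alphabet)
        validate_for_k(tree, spec.k)
        for inst in range(plant.n_instances):
            word = sample_word(tree, rng, rep_p=0.5, rep_cap=2 * spec.k)
            span = plant.span_linebreak and inst == 1
            within = plant.span_linebreak and inst == 0
            start = _place(rng, spec, used, word, span, within)
            if start is None:
                raise SeqrexError(
                    f"could not place an instance of {plant.pattern!r}: "
                    "bins too small or too crowded")
            j, off = start
            texts[j][off:off + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)
            used[j].append((off, off + len(word)))
            truth.append(TruthRecord(j, _record_id(j, digits), off,
                                     off + len(word), word, plant.pattern))

    bin_paths = []
    for j, arr in enumerate(texts):
        p = out_dir / f"bin_{j:0{digits}d}.fa"
        write_fasta(p, [(_record_id(j, digits), arr.tobytes().decode())],
                    spec.line_width)
        bin_paths.append(p)

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("bin_index\trecord_id\tstart0\tend0\tplanted_word\tpattern\n")
        for t in truth:
            fh.write(f"{t.bin_index}\t{t.record_id}\t{t.start}\t{t.end}"
                     f"\t{t.planted_word}\t{t.source_pattern}\n")
    return SimResult(bin_paths, truth_path, truth)


def _place(rng, spec: SimSpec, used, word: str, span: bool, within: bool):
    """Uniform non-overlapping offset; optionally force the occurrence to
    cross (span) or not cross (within) a line boundary."""
    w = spec.line_width
    n = len(word)
    if within and n > w:
        within = False  # a word longer than one line necessarily spans
    for _ in range(2000):
        j = int(rng.integers(spec.n_bins))
        off = int(rng.integers(0, spec.bin_chars - n + 1))
        col = off % w
        if span and col + n <= w:
            continue
        if within and col + n > w:
            continue
        if any(off < e and off + n > s for s, e in used[j]):
            continue
        return j, off
    return None
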