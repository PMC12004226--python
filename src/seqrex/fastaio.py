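"""FASTA utilities: reading, wrapped writing, and database binning."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

from Bio import SeqIO

DEFAULT_LINE_WIDTH = 70


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; multi-line records are concatenated."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]],
                width: int = DEFAULT_LINE_WIDTH) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def split_fasta(input_path: str | Path, u: int, out_dir: str | Path,
                policy: str = "round_robin",
                width: int = DEFAULT_LINE_WIDTH) -> list[Path]:
    """Split one FASTA database into u bin files.

    ``round_robin`` deals records out in input order; ``balanced_chars``
    greedily assigns each record to the currently smallest bin. Records are
    never modified and each lands in exactly one bin.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    records = read_fasta(input_path)
    if not records:
        raise ValueError(f"{input_path}: no FASTA records")
    bins: list[list[tuple[str, str]]] = [[] for _ in range(u)]
    if policy == "round_robin":
        for i, rec in enumerate(records):
            bins[i % u].append(rec)
    elif policy == "balanced_chars":
        sizes = [0] * u
        for rec in records:
            j = sizes.index(min(sizes))
            bins[j].append(rec)
            sizes[j] += len(rec[1])
    else:
        raise ValueError(f"unknown split policy {policy!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digits = max(3, len(str(u - 1)))
    paths = []
    for j, recs in enumerate(bins):
        p = out_dir / f"bin_{j:0{digits}d}.fa"
        write_fasta(p, recs, width)
        paths.append(p)
    return paths
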