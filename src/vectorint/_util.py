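"""Small shared helpers: sequence ops, rounding, interval merging, FASTA/FASTQ."""

from __future__ import annotations

import math
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do (not banker's)."""
    factor = 10.0 ** ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor
    r = math.copysign(r, x)
    return int(r) if ndigits <= 0 else r


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge half-open intervals, joining any separated by <= max_gap."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]


# --- minimal FASTA / FASTQ text I/O -----------------------------------------
# FASTQ writing is kept as plain text for speed on large simulated libraries;
# FASTA parsing accepts multi-line records.


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fastq_pair(
    pairs: Iterable[tuple[str, str, str]], path1: str, path2: str, quality_char: str = "I"
) -> None:
    """Write read pairs (name, seq1, seq2) as two Phred+33 FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{quality_char * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{quality_char * len(s2)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            fh.readline()
            out.append((header[1:].rstrip().split()[0], seq))
    return out
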