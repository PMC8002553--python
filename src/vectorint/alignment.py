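"""Fixture-scale read mapping, SAM I/O and mapping statistics.

The mapper is a deliberately small seed-and-extend aligner over a joint k-mer
index of all targets (chromosomes plus vector). It reports soft-clips at read
ends, distinguishes unique / ambiguous / unmapped placements, and pairs mates,
which is all the downstream junction logic needs. It is not a general-purpose
aligner; external SAM from a real short-read mapper is accepted through
:func:`read_sam` as long as mate fields and CIGARs are populated.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from vectorint._util import revcomp, round_half_up

logger = logging.getLogger(__name__)

DEFAULT_K = 20
_QUERY_OPS = set("MIS=X")
_TARGET_OPS = set("MD=XN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AlignmentRecord:
    """One read placement, SAM-convention: seq/cigar in target orientation."""

    name: str
    target: Optional[str]
    start: int                       # 0-based on target; -1 when unmapped
    strand: str                      # '+' or '-'
    cigar: list[tuple[str, int]]     # ops among M/I/D/S, clips only at ends
    seq: str                         # stored in target orientation
    status: str                      # unique | ambiguous | unmapped
    mate_target: Optional[str] = None
    mate_start: int = -1
    is_proper_pair: bool = False
    mate_strand: str = "+"
    read_index: int = 0              # 1 or 2 within the pair, 0 if unpaired

    def __post_init__(self) -> None:
        if self.cigar:
            qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError("CIGAR query length does not match read length")
            for op, _n in self.cigar[1:-1]:
                if op == "S":
                    raise ValueError("soft-clips only allowed at read ends")

    @property
    def read_length(self) -> int:
        return len(self.seq)

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def end(self) -> int:
        """Exclusive alignment end on the target."""
        return self.start + sum(n for op, n in self.cigar if op in _TARGET_OPS)

    @property
    def is_mapped(self) -> bool:
        return self.status != "unmapped"

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Target intervals covered by M/=/X ops (soft-clips excluded)."""
        blocks = []
        pos = self.start
        for op, n in self.cigar:
            if op in "M=X":
                blocks.append((pos, pos + n))
                pos += n
            elif op in "DN":
                pos += n
        return blocks


@dataclass(frozen=True)
class MappingStats:
    """Per-line mapping summary (full precision; rounding only at report time)."""

    total_raw_reads: int
    total_mapped_length_bp: int
    reference_length_bp: int
    read_pairs_mapped: int
    proper_pairs_mapped: int
    average_insert_size: float

    @property
    def average_coverage(self) -> float:
        return self.total_mapped_length_bp / self.reference_length_bp

    @property
    def mapped_percent(self) -> float:
        return 100.0 * self.read_pairs_mapped / self.total_raw_reads

    def report(self) -> dict:
        """Printed-precision view: coverage to integer, percent to 1 dp."""
        return {
            "total_raw_reads": self.total_raw_reads,
            "total_mapped_length_bp": self.total_mapped_length_bp,
            "average_coverage": int(round_half_up(self.average_coverage)),
            "read_pairs_mapped": self.read_pairs_mapped,
            "proper_pairs_mapped": self.proper_pairs_mapped,
            "mapped_percent": round_half_up(self.mapped_percent, 1),
            "average_insert_size": round_half_up(self.average_insert_size, 1)
            if not math.isnan(self.average_insert_size) else None,
        }


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------


class SeedIndex:
    """Joint k-mer occurrence index over all targets (genome + vector)."""

    def __init__(self, targets: dict[str, str], k: int) -> None:
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        if not targets:
            raise ValueError("empty sequence set")
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate target names")
        self.k = k
        self.targets = dict(targets)
        self.names = list(targets)
        index: dict[str, list[tuple[int, int]]] = {}
        for tid, (_name, seq) in enumerate(targets.items()):
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((tid, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self._index.get(kmer, [])

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._index

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self._index.values())


def build_index(targets: dict[str, str] | Sequence[tuple[str, str]],
                k: int = DEFAULT_K) -> SeedIndex:
    """Build a joint seed index; duplicate names or an empty set are rejected."""
    if not isinstance(targets, dict):
        names = [n for n, _ in targets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate target names")
        targets = dict(targets)
    return SeedIndex(targets, k)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def _extend(read: str, target: str, diag: int, seed_lo: int, seed_hi: int
            ) -> tuple[int, int]:
    """Extend a seeded diagonal; returns matched read interval [lo, hi).

    Walks outward from the seed-supported core allowing isolated mismatches
    when the following three bases agree (substitution tolerance); stops
    otherwise, which pins junction boundaries at the last matching base.
    """
    n = len(read)
    m = len(target)

    def matches(i: int) -> bool:
        t = diag + i
        return 0 <= i < n and 0 <= t < m and read[i] == target[t]

    lo, hi = seed_lo, seed_hi
    i = hi
    while i < n:
        if matches(i):
            hi = i + 1
            i += 1
        elif matches(i + 1) and matches(i + 2) and matches(i + 3):
            hi = i + 4  # isolated substitution absorbed
            i += 4
        else:
            break
    i = lo - 1
    while i >= 0:
        if matches(i):
            lo = i
            i -= 1
        elif i >= 3 and matches(i - 1) and matches(i - 2) and matches(i - 3):
            lo = i - 3
            i -= 4
        else:
            break
    return lo, hi


def _candidates(seq: str, index: SeedIndex, max_diags: int = 8
                ) -> list[tuple[str, int, int, int]]:
    """Seed-vote candidate diagonals: (strand, tid, diag, votes-core)."""
    k = index.k
    n = len(seq)
    offsets = list(range(0, n - k + 1, max(1, (n - k) // 4 or 1)))
    if offsets[-1] != n - k:
        offsets.append(n - k)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        votes: dict[tuple[int, int], list[int]] = {}
        for off in offsets:
            for tid, pos in index.lookup(s[off : off + k]):
                votes.setdefault((tid, pos - off), []).append(off)
        for (tid, diag), offs in votes.items():
            out.append((strand, tid, diag, min(offs), max(offs) + k, len(offs)))
    out.sort(key=lambda c: -c[5])
    return [(st, tid, diag, lo, hi) for st, tid, diag, lo, hi, _ in out[:max_diags]]


def map_read(name: str, seq: str, index: SeedIndex) -> AlignmentRecord:
    """Seed-vote then extend; ties between distinct best placements -> ambiguous.

    The returned record follows SAM conventions: for '-' placements the stored
    sequence and CIGAR are in target-forward orientation.
    """
    if len(seq) < index.k:
        return _unmapped(name, seq)
    best: list[tuple[int, str, int, int, int, int]] = []  # score, strand, tid, start, lo, hi
    for strand, tid, diag, seed_lo, seed_hi in _candidates(seq, index):
        oriented = seq if strand == "+" else revcomp(seq)
        target = index.targets[index.names[tid]]
        lo, hi = _extend(oriented, target, diag, seed_lo, seed_hi)
        score = hi - lo
        best.append((score, strand, tid, diag + lo, lo, hi))
    if not best:
        return _unmapped(name, seq)
    best.sort(key=lambda b: -b[0])
    score, strand, tid, start, lo, hi = best[0]
    distinct_ties = {
        (b[2], b[3], b[1]) for b in best if b[0] == score
    }
    status = "ambiguous" if len(distinct_ties) > 1 else "unique"
    oriented = seq if strand == "+" else revcomp(seq)
    cigar: list[tuple[str, int]] = []
    if lo:
        cigar.append(("S", lo))
    cigar.append(("M", hi - lo))
    if len(seq) - hi:
        cigar.append(("S", len(seq) - hi))
    return AlignmentRecord(
        name=name, target=index.names[tid], start=start, strand=strand,
        cigar=cigar, seq=oriented, status=status,
    )


def _unmapped(name: str, seq: str) -> AlignmentRecord:
    return AlignmentRecord(
        name=name, target=None, start=-1, strand="+", cigar=[],
        seq=seq, status="unmapped",
    )


def _exact_hits(seq: str, index: SeedIndex) -> list[tuple[str, int, int]]:
    """Fast path: full-length exact placements found from the first k-mer."""
    hits = []
    k = index.k
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for tid, pos in index.lookup(s[:k]):
            target = index.targets[index.names[tid]]
            if target[pos : pos + len(s)] == s:
                hits.append((strand, tid, pos))
    return hits


def map_read_fast(name: str, seq: str, index: SeedIndex) -> AlignmentRecord:
    """map_read with an exact-match fast path (identical contract)."""
    if len(seq) >= index.k:
        hits = _exact_hits(seq, index)
        if len(hits) == 1:
            strand, tid, pos = hits[0]
            oriented = seq if strand == "+" else revcomp(seq)
            return AlignmentRecord(
                name=name, target=index.names[tid], start=pos, strand=strand,
                cigar=[("M", len(seq))], seq=oriented, status="unique",
            )
        if len(hits) > 1:
            strand, tid, pos = hits[0]
            oriented = seq if strand == "+" else revcomp(seq)
            return AlignmentRecord(
                name=name, target=index.names[tid], start=pos, strand=strand,
                cigar=[("M", len(seq))], seq=oriented, status="ambiguous",
            )
    return map_read(name, seq, index)


def map_pairs(
    pairs: Iterable[tuple[str, str, str]],
    index: SeedIndex,
    max_insert: int = 2000,
) -> list[AlignmentRecord]:
    """Map mate pairs and fill in mate/proper-pair fields.

    A pair is proper when both mates map uniquely to the same target in
    opposite, inward orientations with an outer distance within ``max_insert``.
    """
    out: list[AlignmentRecord] = []
    for name, s1, s2 in pairs:
        r1 = map_read_fast(name, s1, index)
        r2 = map_read_fast(name, s2, index)
        r1.read_index, r2.read_index = 1, 2
        for a, b in ((r1, r2), (r2, r1)):
            a.mate_target = b.target
            a.mate_start = b.start
            a.mate_strand = b.strand
        proper = False
        if (
            r1.status == "unique" and r2.status == "unique"
            and r1.target == r2.target and r1.strand != r2.strand
        ):
            fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
            tlen = rev.end - fwd.start
            proper = 0 < tlen <= max_insert and fwd.start <= rev.end
        r1.is_proper_pair = r2.is_proper_pair = proper
        out.append(r1)
        out.append(r2)
    return out


def insert_size(r1: AlignmentRecord, r2: AlignmentRecord) -> Optional[int]:
    """Outer distance between mate extremes; None across targets/unmapped."""
    if not (r1.is_mapped and r2.is_mapped) or r1.target != r2.target:
        return None
    return max(r1.end, r2.end) - min(r1.start, r2.start)


# ---------------------------------------------------------------------------
# mapping statistics
# ---------------------------------------------------------------------------


def compute_mapping_stats(
    alignments: Optional[Sequence[AlignmentRecord]] = None,
    *,
    reference_length_bp: int,
    total_raw_reads: int,
    total_mapped_length_bp: Optional[int] = None,
    read_pairs_mapped: Optional[int] = None,
    proper_pairs_mapped: int = 0,
    average_insert_size: float = float("nan"),
) -> MappingStats:
    """Mapping summary, from alignments or directly from printed counts.

    'Total length of the mapped reads' sums full read lengths of uniquely
    mapped records (not clipped-aligned bases); ambiguous placements are
    counted as mapped for pairing purposes but excluded from coverage.
    """
    if reference_length_bp <= 0:
        raise ValueError("reference_length_bp must be > 0")
    if total_raw_reads <= 0:
        raise ValueError("total_raw_reads must be > 0")
    if alignments is not None:
        total_mapped_length_bp = sum(
            r.read_length for r in alignments if r.status == "unique"
        )
        by_name: dict[str, list[AlignmentRecord]] = {}
        for r in alignments:
            by_name.setdefault(r.name, []).append(r)
        read_pairs_mapped = 0
        proper_pairs_mapped = 0
        sizes = []
        for recs in by_name.values():
            if len(recs) == 2 and all(r.is_mapped for r in recs):
                read_pairs_mapped += 1
                if recs[0].is_proper_pair:
                    proper_pairs_mapped += 1
                    isz = insert_size(recs[0], recs[1])
                    if isz is not None:
                        sizes.append(isz)
        average_insert_size = (sum(sizes) / len(sizes)) if sizes else float("nan")
    if total_mapped_length_bp is None or read_pairs_mapped is None:
        raise ValueError("need alignments or explicit counts")
    return MappingStats(
        total_raw_reads=total_raw_reads,
        total_mapped_length_bp=total_mapped_length_bp,
        reference_length_bp=reference_length_bp,
        read_pairs_mapped=read_pairs_mapped,
        proper_pairs_mapped=proper_pairs_mapped,
        average_insert_size=average_insert_size,
    )


# ---------------------------------------------------------------------------
# SAM I/O (text SAM subset via pysam)
# ---------------------------------------------------------------------------


@dataclass
class SamReadResult:
    records: list[AlignmentRecord]
    skipped: int = 0
    target_lengths: dict[str, int] = field(default_factory=dict)


def write_sam(records: Sequence[AlignmentRecord], path: str,
              target_lengths: dict[str, int]) -> None:
    """Write records as text SAM. Status is encoded in MAPQ (60/0/unmapped)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in target_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        tid_of = {n: i for i, n in enumerate(target_lengths)}
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            flag = 0
            if r.read_index:
                flag |= 0x1
                flag |= 0x40 if r.read_index == 1 else 0x80
            if r.status == "unmapped":
                flag |= 0x4
            else:
                if r.strand == "-":
                    flag |= 0x10
                if r.is_proper_pair:
                    flag |= 0x2
            if r.mate_target is None and r.read_index:
                flag |= 0x8
            elif r.mate_strand == "-":
                flag |= 0x20
            a.flag = flag
            if r.is_mapped:
                a.reference_id = tid_of[r.target]
                a.reference_start = r.start
                a.mapping_quality = 60 if r.status == "unique" else 0
                a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            else:
                a.reference_id = -1
                a.reference_start = -1
            if r.mate_target is not None:
                a.next_reference_id = tid_of[r.mate_target]
                a.next_reference_start = r.mate_start
            fh.write(a)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(text: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise ValueError(f"unparseable CIGAR {text!r}")
    return ops


def read_sam(path: str) -> SamReadResult:
    """Read a text SAM subset back into AlignmentRecords.

    Parsed directly from text (htslib refuses records it considers malformed,
    but the contract here is to skip and count them): records whose CIGAR does
    not account for the stored sequence length are dropped with a logged
    warning. A header-less file is rejected. MAPQ 0 on a mapped record is
    interpreted as ambiguous, matching common multi-mapping conventions.
    """
    lengths: dict[str, int] = {}
    records: list[AlignmentRecord] = []
    skipped = 0
    saw_header = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                saw_header = True
                if line.startswith("@SQ"):
                    tags = dict(
                        f.split(":", 1) for f in line.split("\t")[1:] if ":" in f
                    )
                    lengths[tags["SN"]] = int(tags["LN"])
                continue
            if not saw_header or not lengths:
                raise ValueError("SAM file has no header with @SQ lines")
            fields = line.split("\t")
            if len(fields) < 11:
                skipped += 1
                logger.warning("skipping truncated SAM line")
                continue
            name, flag_s, rname, pos_s, mapq_s, cigar_s = fields[:6]
            rnext, pnext_s, _tlen, seq = fields[6:10]
            flag = int(flag_s)
            unmapped = bool(flag & 0x4) or rname == "*"
            if seq == "*":
                seq = ""
            if not unmapped:
                try:
                    cig = _parse_cigar(cigar_s)
                except ValueError:
                    skipped += 1
                    logger.warning("skipping %s: bad CIGAR", name)
                    continue
                qlen = sum(n for op, n in cig if op in _QUERY_OPS)
                if qlen != len(seq) or not seq:
                    skipped += 1
                    logger.warning(
                        "skipping %s: CIGAR/sequence length mismatch", name
                    )
                    continue
                rec = AlignmentRecord(
                    name=name,
                    target=rname,
                    start=int(pos_s) - 1,
                    strand="-" if flag & 0x10 else "+",
                    cigar=cig,
                    seq=seq,
                    status="ambiguous" if int(mapq_s) == 0 else "unique",
                )
            else:
                rec = _unmapped(name, seq)
            if flag & 0x1:
                rec.read_index = 1 if flag & 0x40 else 2
                rec.is_proper_pair = bool(flag & 0x2) and not unmapped
                if rnext != "*":
                    rec.mate_target = rname if rnext == "=" else rnext
                    rec.mate_start = int(pnext_s) - 1
                    rec.mate_strand = "-" if flag & 0x20 else "+"
            records.append(rec)
    return SamReadResult(records=records, skipped=skipped, target_lengths=lengths)


# ---------------------------------------------------------------------------
# GFF3 (annotation input for locus context)
# ---------------------------------------------------------------------------


def read_gff3(path: str) -> list[dict]:
    """Minimal GFF3 reader: seqid/type/start0/end/strand/attributes."""
    rows: list[dict] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            rows.append(
                {
                    "seqid": parts[0],
                    "type": parts[2],
                    "start": int(parts[3]) - 1,  # GFF is 1-based inclusive
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "attrs": attrs,
                }
            )
    return rows


def write_gff3(rows: Sequence[tuple[str, str, str, int, int, str, str]],
               path: str) -> None:
    """Write (seqid, source, type, start0, end, strand, attrs) rows as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, strand, attrs in rows:
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


__all__ = [
    "AlignmentRecord", "MappingStats", "SeedIndex", "SamReadResult",
    "build_index", "map_read", "map_read_fast", "map_pairs", "insert_size",
    "compute_mapping_stats", "read_sam", "write_sam", "read_gff3", "write_gff3",
    "DEFAULT_K",
]
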