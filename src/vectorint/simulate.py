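"""Ground-truthed synthetic transformants.

Generates a multi-chromosome haploid reference, a linear vector carrying
host-derived segments (so homology masking is exercised downstream), applies
insertion events drawn from an observed repertoire (target-site duplications,
target deletions, fillers, internal inversions, inverted duplications, tandem
multi-copy inserts, adjacent large deletions), simulates inward-oriented
paired-end reads, and emits assembly-like contigs spanning the locus.

Every mutated genome comes with a :class:`TruthRecord` whose attribution map
explains each base (reference / vector / filler) and can be replayed to
reproduce the genome byte-for-byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from vectorint._util import DNA_ALPHABET, gc_fraction, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

FillerOrigin = Literal["unknown", "external"]  # or "vector-duplicate:<start>-<end>"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedReference:
    """A toy haploid reference: named chromosomes plus optional organelles."""

    sequences: tuple[tuple[str, str], ...]
    seed: int

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.sequences:
            if len(seq) < 1000:
                raise ValueError(f"{name}: sequences must be >= 1000 bp")
            if not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"{name}: alphabet must be within ACGT")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def get(self, name: str) -> str:
        for n, s in self.sequences:
            if n == name:
                return s
        raise KeyError(name)

    def as_dict(self) -> dict[str, str]:
        return dict(self.sequences)


@dataclass(frozen=True)
class VectorTemplate:
    """Linear transforming molecule with feature annotations.

    ``host_derived_segments`` records vector intervals that are verbatim
    copies of the reference, as ``((vec_start, vec_end), chrom, (src_start,
    src_end))`` -- the material that forces homology masking downstream.
    """

    sequence: str
    features: tuple[tuple[str, int, int, str], ...]
    host_derived_segments: tuple[tuple[tuple[int, int], str, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for label, start, end, _strand in self.features:
            if not (0 <= start < end <= n):
                raise ValueError(f"feature {label} outside vector")
        for (vs, ve), _chrom, (ss, se) in self.host_derived_segments:
            if not (0 <= vs < ve <= n):
                raise ValueError("host segment outside vector")
            if ve - vs != se - ss:
                raise ValueError("host segment length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, label: str) -> tuple[int, int]:
        for lab, s, e, _ in self.features:
            if lab == label:
                return s, e
        raise KeyError(label)

    def host_intervals(self) -> list[tuple[int, int]]:
        return [tuple(iv) for iv, _, _ in self.host_derived_segments]


@dataclass(frozen=True)
class InsertionEventSpec:
    """One integration event, expressed in the junction-variant grammar."""

    target: tuple[str, int]
    copies: int = 1
    orientations: tuple[str, ...] = ("+",)  # one of +/- per copy
    left_truncation_bp: int = 0
    right_truncation_bp: int = 0
    tsd_bp: int = 0
    target_deletion_bp: int = 0
    # (side, sequence, declared origin); side in {left, right}
    fillers: tuple[tuple[str, str, str], ...] = ()
    # (kind, (vec_start, vec_end)); kind in {inversion, inverted_duplication}
    internal_events: tuple[tuple[str, tuple[int, int]], ...] = ()
    adjacent_deletion_bp: int = 0
    adjacent_deletion_side: str = "right"

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if len(self.orientations) != self.copies:
            raise ValueError("need one orientation per copy")
        if any(o not in "+-" for o in self.orientations):
            raise ValueError("orientations must be + or -")
        if self.tsd_bp > 0 and self.target_deletion_bp > 0:
            raise ValueError("tsd_bp and target_deletion_bp cannot both be > 0")
        if min(self.left_truncation_bp, self.right_truncation_bp,
               self.tsd_bp, self.target_deletion_bp, self.adjacent_deletion_bp) < 0:
            raise ValueError("event sizes must be >= 0")
        if self.adjacent_deletion_side not in ("left", "right"):
            raise ValueError("adjacent_deletion_side must be left or right")
        if self.adjacent_deletion_side == "left" and self.adjacent_deletion_bp > 0 \
                and self.tsd_bp > 0:
            raise ValueError("left-side adjacent deletion cannot combine with a TSD")
        for side, _seq, _origin in self.fillers:
            if side not in ("left", "right"):
                raise ValueError("filler side must be left or right")


@dataclass
class TruthRecord:
    """Realized event: mutated genome, exact breakpoints, attribution map."""

    line: str
    chrom: str
    position: int                       # insertion point, reference coords
    genome: dict[str, str]              # mutated genome (all targets)
    left_breakpoint: int                # reference coord adjoining insert, left side
    right_breakpoint: int               # reference coord resuming after insert
    insert_start: int                   # mutated-genome coords of locus core
    insert_end: int                     # (includes both TSD copies when present)
    copies: int
    orientations: tuple[str, ...]
    events: list[dict]                  # StructuralVariantCall-equivalent dicts
    right_flank_absent: bool            # insertion runs to the chromosome end
    # attribution: (chrom, mut_start, mut_end, source, detail)
    attribution: list[tuple[str, int, int, str, str]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = {
            "line": self.line,
            "chrom": self.chrom,
            "position": self.position,
            "left_breakpoint": self.left_breakpoint,
            "right_breakpoint": self.right_breakpoint,
            "insert_start": self.insert_start,
            "insert_end": self.insert_end,
            "copies": self.copies,
            "orientations": list(self.orientations),
            "events": self.events,
            "right_flank_absent": self.right_flank_absent,
            "chrom_lengths": {n: len(s) for n, s in self.genome.items()},
        }
        return d


@dataclass(frozen=True)
class ReadSimConfig:
    """Paired-end library parameters (2 x read_length, inward orientation)."""

    read_length: int = 101
    insert_mean: float = 265.0
    insert_sd: float = 30.0
    depth: float = 100.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.insert_mean < 2 * self.read_length:
            warnings.warn(
                "insert_mean below 2x read length: mates will overlap heavily",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# reference and vector construction
# ---------------------------------------------------------------------------


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=n, p=p)
    return arr.tobytes().decode("ascii")


def generate_reference(
    n_chrom: int,
    lengths: Sequence[int],
    gc: float = 0.55,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
) -> SimulatedReference:
    """Generate ``n_chrom`` random chromosomes with the requested GC content.

    Deterministic for a fixed seed; empirical GC converges to ``gc`` for
    lengths of a few kilobases and beyond.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if len(lengths) != n_chrom:
        raise ValueError("need one length per chromosome")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if names is None:
        names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    rng = np.random.default_rng(seed)
    seqs = tuple((name, _random_seq(n, gc, rng)) for name, n in zip(names, lengths))
    return SimulatedReference(sequences=seqs, seed=seed)


def build_vector(
    reference: SimulatedReference,
    length: int,
    feature_plan: Sequence[tuple[str, int, int, str]],
    host_segments: Sequence[tuple[str, int, int, int]] = (),
    gc: float = 0.5,
    seed: int = 0,
) -> VectorTemplate:
    """Assemble a linear vector: random backbone with host segments pasted in.

    ``host_segments`` entries are ``(source_chrom, src_start, src_end,
    vector_start)``; the source interval is copied verbatim into the vector,
    which is what later recruits untransformed genomic reads. Overlapping
    feature plan entries are rejected.
    """
    plan = sorted(feature_plan, key=lambda f: f[1])
    for (l1, s1, e1, _), (l2, s2, e2, _) in zip(plan, plan[1:]):
        if e1 > s2:
            raise ValueError(f"overlapping features {l1} and {l2}")
    rng = np.random.default_rng(seed)
    backbone = list(_random_seq(length, gc, rng))
    recorded = []
    for chrom, ss, se, vstart in host_segments:
        src = reference.get(chrom)
        if not (0 <= ss < se <= len(src)):
            raise ValueError("host segment source outside reference")
        if not (0 <= vstart and vstart + (se - ss) <= length):
            raise ValueError("host segment does not fit in vector")
        backbone[vstart : vstart + (se - ss)] = src[ss:se]
        recorded.append(((vstart, vstart + (se - ss)), chrom, (ss, se)))
    return VectorTemplate(
        sequence="".join(backbone),
        features=tuple((l, s, e, st) for l, s, e, st in feature_plan),
        host_derived_segments=tuple(recorded),
    )


# ---------------------------------------------------------------------------
# filler generation
# ---------------------------------------------------------------------------


def make_filler(
    length: int,
    reference: SimulatedReference,
    vector: VectorTemplate,
    rng: np.random.Generator,
    gc: Optional[float] = None,
    k: int = 20,
    max_tries: int = 200,
) -> str:
    """Random filler sequence sharing no ``k``-mer with reference or vector.

    Rejection sampling makes 'unknown origin' classifiable without any
    database: no alignment seed can anchor the filler anywhere.
    """
    if gc is None:
        gc = gc_fraction("".join(s for _, s in reference.sequences))
    forbidden: set[str] = set()
    for _, seq in reference.sequences:
        for i in range(len(seq) - k + 1):
            forbidden.add(seq[i : i + k])
    vseq = vector.sequence
    for i in range(len(vseq) - k + 1):
        forbidden.add(vseq[i : i + k])

    def shares(seq: str) -> bool:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if w in forbidden or revcomp(w) in forbidden:
                return True
        return False

    for _ in range(max_tries):
        cand = _random_seq(length, gc, rng)
        if length < k or not shares(cand):
            return cand
    raise RuntimeError("could not generate a k-mer-free filler")


# ---------------------------------------------------------------------------
# applying insertion events
# ---------------------------------------------------------------------------


def _copy_sequence_and_events(
    vector: VectorTemplate, event: InsertionEventSpec, copy_idx: int
) -> tuple[str, list[dict]]:
    """Sequence of one vector copy after internal events and truncations."""
    vseq = vector.sequence
    events: list[dict] = []
    s = vseq
    # internal events in vector coordinates, applied right-to-left so earlier
    # coordinates stay valid
    for kind, (a, b) in sorted(event.internal_events, key=lambda e: -e[1][0]):
        if not (0 <= a < b <= len(vseq)):
            raise ValueError("internal event outside vector")
        if kind == "inversion":
            s = s[:a] + revcomp(s[a:b]) + s[b:]
            events.append(
                {"type": "internal_inversion", "target": "vector",
                 "start": a, "end": b, "length": b - a, "orientation": "-"}
            )
        elif kind == "inverted_duplication":
            s = s[:b] + revcomp(vseq[a:b]) + s[b:]
            events.append(
                {"type": "inverted_duplication", "target": "vector",
                 "start": a, "end": b, "length": b - a, "orientation": "-"}
            )
        else:
            raise ValueError(f"unknown internal event kind {kind}")
    if event.orientations[copy_idx] == "-":
        s = revcomp(s)
    return s, events


def apply_insertion(
    reference: SimulatedReference,
    vector: VectorTemplate,
    event: InsertionEventSpec,
    seed: int = 0,
    line: str = "custom",
) -> tuple[dict[str, str], TruthRecord]:
    """Realize one insertion event; returns the mutated genome and its truth.

    Mutated chromosome length = original - target_deletion - adjacent_deletion
    + tsd + total inserted material. With ``tsd_bp > 0`` the duplicated host
    block flanks the insert on both sides in direct orientation.
    """
    chrom, pos = event.target
    cseq = reference.get(chrom)
    if event.left_truncation_bp >= len(vector) or event.right_truncation_bp >= len(vector):
        raise ValueError("truncation exceeds vector length")
    del_total = event.target_deletion_bp + event.adjacent_deletion_bp
    if event.adjacent_deletion_side == "right":
        if pos + del_total > len(cseq):
            raise ValueError("event exceeds chromosome bounds")
    else:
        if pos - event.adjacent_deletion_bp < 0 or pos + event.target_deletion_bp > len(cseq):
            raise ValueError("event exceeds chromosome bounds")
    if not (0 <= pos <= len(cseq)) or pos - event.tsd_bp < 0:
        raise ValueError("event exceeds chromosome bounds")

    events: list[dict] = []
    copy_seqs: list[str] = []
    for ci in range(event.copies):
        s, copy_events = _copy_sequence_and_events(vector, event, ci)
        if ci == 0:
            events.extend(copy_events)  # record internal events once
        copy_seqs.append(s)
    if event.left_truncation_bp:
        copy_seqs[0] = copy_seqs[0][event.left_truncation_bp:]
        events.append(
            {"type": "vector_truncation", "target": "vector", "side": "5p",
             "start": 0, "end": event.left_truncation_bp,
             "length": event.left_truncation_bp}
        )
    if event.right_truncation_bp:
        copy_seqs[-1] = copy_seqs[-1][: len(copy_seqs[-1]) - event.right_truncation_bp]
        events.append(
            {"type": "vector_truncation", "target": "vector", "side": "3p",
             "start": len(vector) - event.right_truncation_bp, "end": len(vector),
             "length": event.right_truncation_bp}
        )
    if event.copies >= 2:
        events.append(
            {"type": "tandem_multicopy", "target": chrom, "start": pos,
             "end": pos, "length": sum(len(s) for s in copy_seqs),
             "copies": event.copies, "orientations": list(event.orientations)}
        )

    left_fill = "".join(seq for side, seq, _ in event.fillers if side == "left")
    right_fill = "".join(seq for side, seq, _ in event.fillers if side == "right")
    for side, seq, origin in event.fillers:
        events.append(
            {"type": "filler_insertion", "target": chrom, "side": side,
             "start": pos, "end": pos, "length": len(seq), "origin": origin,
             "sequence": seq}
        )

    if event.tsd_bp:
        events.append(
            {"type": "target_site_duplication", "target": chrom,
             "start": pos - event.tsd_bp, "end": pos, "length": event.tsd_bp}
        )
    if event.target_deletion_bp:
        events.append(
            {"type": "target_deletion", "target": chrom, "start": pos,
             "end": pos + event.target_deletion_bp,
             "length": event.target_deletion_bp}
        )
    if not event.tsd_bp and not event.target_deletion_bp:
        events.append(
            {"type": "blunt_junction", "target": chrom, "start": pos,
             "end": pos, "length": 0}
        )
    if event.adjacent_deletion_bp:
        if event.adjacent_deletion_side == "right":
            ds = pos + event.target_deletion_bp
            de = ds + event.adjacent_deletion_bp
        else:
            de = pos
            ds = de - event.adjacent_deletion_bp
        events.append(
            {"type": "adjacent_large_deletion", "target": chrom, "start": ds,
             "end": de, "length": event.adjacent_deletion_bp,
             "side": event.adjacent_deletion_side}
        )

    insert = left_fill + "".join(copy_seqs) + right_fill

    # assemble: the TSD flanking copy comes from the host bases immediately
    # upstream of the insertion point, repeated after the insert
    if event.adjacent_deletion_side == "right":
        left_cut = pos
        right_cut = pos + del_total
    else:
        left_cut = pos - event.adjacent_deletion_bp
        right_cut = pos + event.target_deletion_bp
    tsd_seq = cseq[pos - event.tsd_bp : pos] if event.tsd_bp else ""
    # cseq[:left_cut] already ends with the first TSD copy (reference bases
    # [pos - tsd, pos)); the second copy is appended explicitly after the insert
    mutated_chrom = cseq[:left_cut] + insert + tsd_seq + cseq[right_cut:]

    genome = dict(reference.sequences)
    genome[chrom] = mutated_chrom

    left_break = left_cut  # reference coord where the left flank ends
    # seen from the right, the genome resumes with the TSD copy, i.e. at
    # reference coord pos - tsd; hence right - left = -tsd for duplications
    right_break = (pos - event.tsd_bp) if event.tsd_bp else right_cut
    insert_start = left_cut
    insert_end = left_cut + len(insert) + len(tsd_seq)
    # locus core includes the upstream TSD copy so flank-0 contigs carry both
    core_start = insert_start - event.tsd_bp
    right_flank_absent = right_cut >= len(cseq)

    attribution: list[tuple[str, int, int, str, str]] = []
    attribution.append((chrom, 0, left_cut, "reference", f"{chrom}:0-{left_cut}"))
    cursor = left_cut
    if left_fill:
        attribution.append((chrom, cursor, cursor + len(left_fill), "filler", "left"))
        cursor += len(left_fill)
    for ci, s in enumerate(copy_seqs):
        attribution.append(
            (chrom, cursor, cursor + len(s), "vector",
             f"copy{ci}:{event.orientations[ci]}")
        )
        cursor += len(s)
    if right_fill:
        attribution.append((chrom, cursor, cursor + len(right_fill), "filler", "right"))
        cursor += len(right_fill)
    if tsd_seq:
        attribution.append(
            (chrom, cursor, cursor + len(tsd_seq), "reference",
             f"{chrom}:{pos - event.tsd_bp}-{pos}")
        )
        cursor += len(tsd_seq)
    attribution.append(
        (chrom, cursor, len(mutated_chrom), "reference",
         f"{chrom}:{right_cut}-{len(cseq)}")
    )

    truth = TruthRecord(
        line=line,
        chrom=chrom,
        position=pos,
        genome=genome,
        left_breakpoint=left_break,
        right_breakpoint=right_break,
        insert_start=core_start,
        insert_end=insert_end,
        copies=event.copies,
        orientations=event.orientations,
        events=events,
        right_flank_absent=right_flank_absent,
        attribution=attribution,
    )
    return genome, truth


def verify_attribution(truth: TruthRecord, reference: SimulatedReference,
                       vector: VectorTemplate, event: InsertionEventSpec) -> bool:
    """Replay the attribution map and check it rebuilds the mutated genome."""
    mutated = truth.genome[truth.chrom]
    rebuilt: list[str] = []
    fillers = {side: seq for side, seq, _ in event.fillers}
    for chrom, ms, me, source, detail in truth.attribution:
        piece = mutated[ms:me]
        if source == "reference":
            src, span = detail.split(":")
            a, b = map(int, span.split("-"))
            if reference.get(src)[a:b] != piece:
                return False
        elif source == "vector":
            ci = int(detail.split(":")[0][4:])
            expected, _ = _copy_sequence_and_events(vector, event, ci)
            if ci == 0 and event.left_truncation_bp:
                expected = expected[event.left_truncation_bp:]
            if ci == event.copies - 1 and event.right_truncation_bp:
                expected = expected[: len(expected) - event.right_truncation_bp]
            if expected != piece:
                return False
        elif source == "filler":
            if fillers.get(detail, "") != piece:
                return False
        rebuilt.append(piece)
    return "".join(rebuilt) == mutated


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_paired_reads(
    genome: dict[str, str],
    config: ReadSimConfig,
    copy_number: Optional[dict[str, int]] = None,
) -> list[tuple[str, str, str]]:
    """Simulate inward-oriented read pairs; returns (name, read1, read2) tuples.

    Fragment starts are uniform over each target; fragment lengths follow a
    truncated normal (minimum = read length). ``copy_number`` scales per-target
    sampling weight, so a 4-copy organelle receives 4x the nominal depth.
    Substitution errors only. Deterministic per seed.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    names = [n for n in genome if len(genome[n]) >= rl]
    cn = {n: (copy_number or {}).get(n, 1) for n in names}
    weights = np.array([len(genome[n]) * cn[n] for n in names], dtype=float)
    total_weighted = weights.sum()
    n_pairs = int(round(config.depth * total_weighted / (2 * rl)))
    if n_pairs == 0:
        warnings.warn("requested depth yields zero fragments", stacklevel=2)
        return []
    counts = rng.multinomial(n_pairs, weights / total_weighted)
    pairs: list[tuple[str, str, str]] = []
    serial = 0
    for name, count in zip(names, counts):
        seq = genome[name]
        L = len(seq)
        if count == 0:
            continue
        frags = rng.normal(config.insert_mean, config.insert_sd, size=count)
        frags = np.clip(np.rint(frags), rl, L).astype(np.int64)
        starts = rng.integers(0, L - frags + 1)
        flips = rng.random(count) < 0.5
        for i in range(count):
            s = int(starts[i])
            f = int(frags[i])
            fwd = seq[s : s + rl]
            rev = revcomp(seq[s + f - rl : s + f])
            if config.error_rate > 0:
                fwd = _add_errors(fwd, config.error_rate, rng)
                rev = _add_errors(rev, config.error_rate, rng)
            serial += 1
            rname = f"sim:{name}:{serial}"
            if flips[i]:
                pairs.append((rname, rev, fwd))
            else:
                pairs.append((rname, fwd, rev))
    return pairs


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    positions = rng.choice(len(read), size=n_err, replace=False)
    out = list(read)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------


def emit_locus_contig(truth: TruthRecord, flank_bp: int = 2000,
                      name: Optional[str] = None) -> tuple[str, str]:
    """Assembly-stand-in contig: locus core +/- flank, clipped at chrom ends."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    seq = truth.genome[truth.chrom]
    start = max(0, truth.insert_start - flank_bp)
    end = min(len(seq), truth.insert_end + flank_bp)
    return (name or f"contig_{truth.line}", seq[start:end])


# ---------------------------------------------------------------------------
# presets: a fixture per observed event archetype
# ---------------------------------------------------------------------------

HOUSEKEEPING_INTERVAL = ("chr01", 2000, 5527)  # 3527 bp single-copy gene
MARKER_FEATURE = "marker"
VECTOR_LENGTH = 6000

# toy vector layout; the selectable marker is 809 bp and the amp-like
# backbone gene is split across both extremities of the linearized molecule
_VECTOR_FEATURES = (
    ("backbone_gene_5p", 40, 800, "+"),
    ("noncoding", 800, 2000, "+"),
    (MARKER_FEATURE, 2000, 2809, "+"),
    ("promoter_a", 2850, 4050, "+"),
    ("reporter", 4100, 5300, "+"),
    ("terminator", 5350, 5750, "+"),
    ("backbone_gene_3p", 5750, 6000, "+"),
)
_HOST_SEGMENTS = (
    ("chr02", 5000, 6200, 2850),   # promoter_a copied from chr02
    ("chr02", 8000, 8400, 5350),   # terminator copied from chr02
)

PRESET_NAMES = ("T3", "T6", "T12", "T14", "T16", "NT")


@dataclass
class SimulatedLine:
    """Everything one preset produces: inputs, truth, reads, contig."""

    name: str
    reference: SimulatedReference
    vector: VectorTemplate
    event: Optional[InsertionEventSpec]
    truth: Optional[TruthRecord]
    genome: dict[str, str]
    reads: list[tuple[str, str, str]]
    contig: Optional[tuple[str, str]]
    read_config: ReadSimConfig
    gff: list[tuple[str, str, str, int, int, str, str]]  # seqid, src, type, s, e, strand, attrs


def _preset_reference(seed: int, insertion_chrom_len: int) -> SimulatedReference:
    return generate_reference(
        3, [8000, 12000, insertion_chrom_len], gc=0.55, seed=seed,
        names=["chr01", "chr02", "chr03"],
    )


def _preset_event(name: str, reference: SimulatedReference,
                  vector: VectorTemplate, rng: np.random.Generator
                  ) -> Optional[InsertionEventSpec]:
    if name == "NT":
        return None
    if name == "T3":
        # single copy, 518 bp target-site duplication, 83 bp unknown filler at
        # the insert's left junction, 62 bp vector-internal duplicate at the
        # right junction
        return InsertionEventSpec(
            target=("chr03", 10000),
            tsd_bp=518,
            fillers=(
                ("left", make_filler(83, reference, vector, rng), "unknown"),
                ("right", vector.sequence[1481:1543], "vector-duplicate:1481-1543"),
            ),
        )
    if name == "T6":
        # 206 bp target deletion, 64 bp unknown filler at the right junction,
        # 171 bp inversion inside the vector 5' backbone gene
        return InsertionEventSpec(
            target=("chr03", 10000),
            target_deletion_bp=206,
            fillers=(("right", make_filler(64, reference, vector, rng), "unknown"),),
            internal_events=(("inversion", (39, 210)),),
        )
    if name == "T12":
        # tandem multi-copy insertion with one inverted copy
        return InsertionEventSpec(
            target=("chr03", 10000),
            copies=4,
            orientations=("+", "+", "-", "+"),
        )
    if name == "T14":
        # 90 bp inverted duplication of the vector 3' extremity; the right
        # flank of the locus is deleted all the way to the chromosome end
        return InsertionEventSpec(
            target=("chr03", 52000),
            internal_events=(("inverted_duplication", (5828, 5918)),),
            adjacent_deletion_bp=98000,
        )
    if name == "T16":
        # 10 bp target deletion plus a 55 bp filler of external origin
        return InsertionEventSpec(
            target=("chr03", 10000),
            target_deletion_bp=10,
            fillers=(("left", make_filler(55, reference, vector, rng), "external"),),
        )
    raise KeyError(name)


def _preset_gff(name: str) -> list[tuple[str, str, str, int, int, str, str]]:
    """Toy annotation: a gene with an exon over the canonical locus."""
    rows = [
        ("chr01", "sim", "gene", 2000, 5527, "+", "ID=gene_hk;Name=housekeeping"),
        ("chr01", "sim", "exon", 2000, 5527, "+", "Parent=gene_hk"),
    ]
    if name == "T14":
        rows += [
            ("chr03", "sim", "gene", 50500, 54000, "+", "ID=gene_a;Name=locus_gene"),
            ("chr03", "sim", "exon", 50500, 54000, "+", "Parent=gene_a"),
        ]
    else:
        rows += [
            ("chr03", "sim", "gene", 9000, 11500, "+", "ID=gene_a;Name=locus_gene"),
            ("chr03", "sim", "exon", 9000, 11500, "+", "Parent=gene_a"),
            ("chr03", "sim", "gene", 13000, 14500, "+", "ID=gene_b;Name=next_gene"),
        ]
    return rows


def simulate_line(
    preset: str,
    seed: int = 0,
    depth: float = 100.0,
    error_rate: float = 0.0,
    flank_bp: int = 2000,
    event: Optional[InsertionEventSpec] = None,
) -> SimulatedLine:
    """Build one full fixture for a preset (or a custom event)."""
    if preset not in PRESET_NAMES and event is None and preset != "custom":
        raise KeyError(f"unknown preset {preset!r}")
    ss = np.random.SeedSequence(entropy=(seed, PRESET_NAMES.index(preset)
                                         if preset in PRESET_NAMES else 99))
    s_ref, s_vec, s_fill, s_reads = (int(s.generate_state(1)[0])
                                     for s in ss.spawn(4))
    chrom3_len = 150000 if preset == "T14" else 20000
    reference = _preset_reference(s_ref, chrom3_len)
    vector = build_vector(
        reference, VECTOR_LENGTH, _VECTOR_FEATURES, _HOST_SEGMENTS, seed=s_vec
    )
    rng = np.random.default_rng(s_fill)
    if event is None:
        event = _preset_event(preset, reference, vector, rng)
    read_config = ReadSimConfig(depth=depth, error_rate=error_rate, seed=s_reads)
    if event is None:
        genome = reference.as_dict()
        truth = None
        contig = None
    else:
        genome, truth = apply_insertion(reference, vector, event, line=preset)
        contig = emit_locus_contig(truth, flank_bp=flank_bp)
    reads = simulate_paired_reads(genome, read_config)
    return SimulatedLine(
        name=preset,
        reference=reference,
        vector=vector,
        event=event,
        truth=truth,
        genome=genome,
        reads=reads,
        contig=contig,
        read_config=read_config,
        gff=_preset_gff(preset),
    )
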