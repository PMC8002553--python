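"""Junction evidence extraction and insertion-locus calling.

Two evidence channels localize a genome--vector junction:

- discordant pairs: one mate uniquely on a chromosome, the other uniquely on
  the vector (breakpoint precision ~ one insert size);
- split reads: a soft-clipped tail of a uniquely mapped read that remaps
  uniquely to the other target, giving a base-exact breakpoint at the clip
  boundary.

Evidence is clustered along the genome into locus calls with per-side support
and a completeness status (both_ends / left_only / right_only).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from vectorint.alignment import AlignmentRecord, SeedIndex, map_read
from vectorint.coverage import CoverageProfile

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 530      # cluster gap: ~2x mean insert size
DEFAULT_MIN_SUPPORT = 3   # evidence items per reported locus
DEFAULT_MIN_CLIP = 15     # minimal soft-clip length worth remapping
VECTOR_END_MARGIN = 150   # vector coords closer than this to an end engage it


@dataclass(frozen=True)
class JunctionEvidence:
    """One read pair or clipped read linking genome and vector coordinates."""

    kind: str                       # discordant_pair | split_read
    chrom: str
    genome_pos: int                 # breakpoint estimate (exact for splits)
    genome_interval: tuple[int, int]  # uncertainty interval
    side: str                       # left | right (of the insert, genome coords)
    vector_pos: int
    vector_strand: str
    read_name: str
    precision: str                  # exact | interval

    def __post_init__(self) -> None:
        # clipped_end: a soft-clip whose tail maps nowhere (e.g. filler DNA);
        # used only to refine breakpoints of clusters supported by the other
        # two kinds, never to seed a locus
        if self.kind not in ("discordant_pair", "split_read", "clipped_end"):
            raise ValueError("bad evidence kind")
        if self.side not in ("left", "right"):
            raise ValueError("bad evidence side")


@dataclass
class InsertionLocusCall:
    """Clustered junction evidence at one genomic locus."""

    chrom: str
    left_breakpoint: Optional[int]
    right_breakpoint: Optional[int]
    left_precision: str = "absent"     # exact | interval | absent
    right_precision: str = "absent"
    left_support: tuple[int, int] = (0, 0)    # (pairs, splits)
    right_support: tuple[int, int] = (0, 0)
    left_vector_end: Optional[str] = None     # 5p | 3p | internal
    right_vector_end: Optional[str] = None
    status: str = "both_ends"
    context: dict = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.left_support) + sum(self.right_support)

    @property
    def anchor_pos(self) -> int:
        cands = [b for b in (self.left_breakpoint, self.right_breakpoint)
                 if b is not None]
        return min(cands)

    def to_json_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "left_breakpoint": self.left_breakpoint,
            "right_breakpoint": self.right_breakpoint,
            "left_precision": self.left_precision,
            "right_precision": self.right_precision,
            "left_support": list(self.left_support),
            "right_support": list(self.right_support),
            "left_vector_end": self.left_vector_end,
            "right_vector_end": self.right_vector_end,
            "status": self.status,
            "context": self.context,
        }


def _overlaps_mask(start: int, end: int, mask: Sequence[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in mask)


# ---------------------------------------------------------------------------
# evidence extraction
# ---------------------------------------------------------------------------


def extract_junction_pairs(
    alignments: Sequence[AlignmentRecord],
    vector_name: str,
    mask: Sequence[tuple[int, int]] = (),
    insert_size_hint: int = 265,
) -> list[JunctionEvidence]:
    """Pairs with one mate uniquely on a chromosome, the other on the vector.

    Mates overlapping a masked (host-shared) vector interval are excluded --
    those junctions are not diagnostic of vector presence. Output is sorted
    by chromosome then position.
    """
    by_name: dict[str, list[AlignmentRecord]] = {}
    for r in alignments:
        if r.read_index:
            by_name.setdefault(r.name, []).append(r)
    out: list[JunctionEvidence] = []
    for name, recs in by_name.items():
        if len(recs) != 2:
            continue
        a, b = recs
        if a.status != "unique" or b.status != "unique":
            continue
        if (a.target == vector_name) == (b.target == vector_name):
            continue
        gmate, vmate = (a, b) if b.target == vector_name else (b, a)
        if _overlaps_mask(vmate.start, vmate.end, mask):
            continue
        if gmate.strand == "+":
            side = "left"
            interval = (gmate.end, gmate.end + insert_size_hint)
            pos = gmate.end
        else:
            side = "right"
            interval = (max(0, gmate.start - insert_size_hint), gmate.start)
            pos = gmate.start
        out.append(
            JunctionEvidence(
                kind="discordant_pair",
                chrom=gmate.target,
                genome_pos=pos,
                genome_interval=interval,
                side=side,
                vector_pos=vmate.start if vmate.strand == "+" else vmate.end,
                vector_strand=vmate.strand,
                read_name=name,
                precision="interval",
            )
        )
    out.sort(key=lambda e: (e.chrom, e.genome_pos))
    return out


def extract_split_reads(
    alignments: Sequence[AlignmentRecord],
    index: SeedIndex,
    vector_name: str,
    mask: Sequence[tuple[int, int]] = (),
    min_clip: int = DEFAULT_MIN_CLIP,
) -> list[JunctionEvidence]:
    """Remap soft-clipped tails across the genome/vector boundary.

    A clip of >= ``min_clip`` bases from a uniquely mapped read that remaps
    uniquely to the other target yields exact evidence at the clip boundary.
    Ambiguously remapping clips (e.g. inside host-shared vector segments) are
    dropped and counted.
    """
    if min_clip < 10:
        raise ValueError("min_clip must be >= 10")
    out: list[JunctionEvidence] = []
    n_ambiguous = 0
    for r in alignments:
        if r.status != "unique" or r.target is None:
            continue
        primary_is_vector = r.target == vector_name
        for clip_side in ("left", "right"):
            clip_len = r.left_clip if clip_side == "left" else r.right_clip
            if clip_len < min_clip:
                continue
            clip_seq = r.seq[:clip_len] if clip_side == "left" else r.seq[-clip_len:]
            hit = map_read(r.name + f"/{clip_side}clip", clip_seq, index)
            if hit.status == "ambiguous":
                n_ambiguous += 1
                continue
            if hit.status == "unmapped" or hit.target is None:
                continue
            if (hit.target == vector_name) == primary_is_vector:
                continue  # clip lands on the same side as the primary
            # require the clip to remap (nearly) in full: partial clip
            # alignments do not pin the junction
            if (hit.end - hit.start) < clip_len - 2:
                continue
            ev = _split_evidence(r, hit, clip_side, vector_name, mask)
            if ev is not None:
                out.append(ev)
    if n_ambiguous:
        logger.info("split-read remapping: %d ambiguous clips dropped", n_ambiguous)
    out.sort(key=lambda e: (e.chrom, e.genome_pos))
    return out


def _split_evidence(
    primary: AlignmentRecord,
    clip_hit: AlignmentRecord,
    clip_side: str,
    vector_name: str,
    mask: Sequence[tuple[int, int]],
) -> Optional[JunctionEvidence]:
    """Junction coordinates from a primary alignment and its remapped clip.

    All geometry is in target-forward convention: the clip boundary of the
    primary abuts the junction; which genome side it is follows from whether
    the genome-aligned piece precedes or follows the vector piece in the
    stored orientation.
    """
    if primary.target == vector_name:
        # clip is genomic; vector boundary comes from the primary
        if _overlaps_mask(primary.start, primary.end, mask):
            return None
        vpos = primary.end if clip_side == "right" else primary.start
        gstrand = clip_hit.strand
        if clip_side == "right":
            # layout: vector | genome-piece
            side = "right" if gstrand == "+" else "left"
            gpos = clip_hit.start if gstrand == "+" else clip_hit.end
        else:
            # layout: genome-piece | vector
            side = "left" if gstrand == "+" else "right"
            gpos = clip_hit.end if gstrand == "+" else clip_hit.start
        chrom = clip_hit.target
        vstrand = "+" if gstrand == primary.strand else "-"
    else:
        if _overlaps_mask(clip_hit.start, clip_hit.end, mask):
            return None
        if clip_side == "right":
            side = "left"
            gpos = primary.end
            vpos = clip_hit.start if clip_hit.strand == "+" else clip_hit.end
        else:
            side = "right"
            gpos = primary.start
            vpos = clip_hit.end if clip_hit.strand == "+" else clip_hit.start
        chrom = primary.target
        vstrand = "+" if clip_hit.strand == primary.strand else "-"
    return JunctionEvidence(
        kind="split_read",
        chrom=chrom,
        genome_pos=gpos,
        genome_interval=(gpos, gpos),
        side=side,
        vector_pos=vpos,
        vector_strand=vstrand,
        read_name=primary.name,
        precision="exact",
    )


def extract_clipped_ends(
    alignments: Sequence[AlignmentRecord],
    vector_name: str,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> list[JunctionEvidence]:
    """Breakpoint hints from soft-clip boundaries on chromosome alignments.

    Junctions abutting filler DNA leave clips that remap nowhere (the filler
    matches neither target), yet the clip boundary still marks the junction
    exactly. These hints refine cluster breakpoints but carry no locus
    support on their own.
    """
    out: list[JunctionEvidence] = []
    for r in alignments:
        if r.status != "unique" or r.target is None or r.target == vector_name:
            continue
        if r.right_clip >= min_clip:
            out.append(JunctionEvidence(
                kind="clipped_end", chrom=r.target, genome_pos=r.end,
                genome_interval=(r.end, r.end), side="left", vector_pos=-1,
                vector_strand="+", read_name=r.name, precision="exact",
            ))
        if r.left_clip >= min_clip:
            out.append(JunctionEvidence(
                kind="clipped_end", chrom=r.target, genome_pos=r.start,
                genome_interval=(r.start, r.start), side="right", vector_pos=-1,
                vector_strand="+", read_name=r.name, precision="exact",
            ))
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_evidence(
    evidence: Sequence[JunctionEvidence],
    vector_length: int,
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
    clip_hints: Sequence[JunctionEvidence] = (),
) -> list[InsertionLocusCall]:
    """Single-linkage clustering along the genome into locus calls.

    Within a cluster, evidence is divided into left/right side groups; each
    side's breakpoint is the modal exact split-read coordinate when present,
    otherwise the midpoint of the pair intervals. Clusters below
    ``min_support`` total evidence are dropped (and logged).
    """
    calls: list[InsertionLocusCall] = []
    ev_sorted = sorted(evidence, key=lambda e: (e.chrom, e.genome_pos))
    cluster: list[JunctionEvidence] = []

    def flush() -> None:
        if not cluster:
            return
        if len(cluster) < min_support:
            logger.info(
                "dropping cluster %s:%d with support %d < %d",
                cluster[0].chrom, cluster[0].genome_pos, len(cluster), min_support,
            )
            return
        lo = min(e.genome_interval[0] for e in cluster) - window
        hi = max(e.genome_interval[1] for e in cluster) + window
        hints = [h for h in clip_hints
                 if h.chrom == cluster[0].chrom and lo <= h.genome_pos <= hi]
        calls.append(_make_call(cluster, vector_length, hints))

    for ev in ev_sorted:
        if cluster and (
            ev.chrom != cluster[-1].chrom
            or ev.genome_pos - cluster[-1].genome_pos > window
        ):
            flush()
            cluster = []
        cluster.append(ev)
    flush()
    return calls


def _side_breakpoint(group: list[JunctionEvidence],
                     hints: list[JunctionEvidence]) -> tuple[Optional[int], str]:
    exact = [e.genome_pos for e in group if e.precision == "exact"]
    if exact:
        return Counter(exact).most_common(1)[0][0], "exact"
    # corroborated clip boundaries: need at least two agreeing reads
    hint_pos = Counter(h.genome_pos for h in hints)
    if hint_pos:
        pos, n = hint_pos.most_common(1)[0]
        if n >= 2 and group:
            return pos, "exact"
    if group:
        mids = [sum(e.genome_interval) / 2 for e in group]
        return int(round(float(np.mean(mids)))), "interval"
    return None, "absent"


def _vector_end(group: list[JunctionEvidence], vector_length: int
                ) -> Optional[str]:
    if not group:
        return None
    pos = Counter(e.vector_pos for e in group).most_common(1)[0][0]
    if pos <= VECTOR_END_MARGIN:
        return "5p"
    if pos >= vector_length - VECTOR_END_MARGIN:
        return "3p"
    return "internal"


def _make_call(cluster: list[JunctionEvidence], vector_length: int,
               hints: list[JunctionEvidence] = []) -> InsertionLocusCall:
    left = [e for e in cluster if e.side == "left"]
    right = [e for e in cluster if e.side == "right"]
    lbp, lprec = _side_breakpoint(left, [h for h in hints if h.side == "left"])
    rbp, rprec = _side_breakpoint(right, [h for h in hints if h.side == "right"])
    if left and right:
        status = "both_ends"
    elif left:
        status = "left_only"
    else:
        status = "right_only"
    count = lambda grp, kind: sum(1 for e in grp if e.kind == kind)  # noqa: E731
    return InsertionLocusCall(
        chrom=cluster[0].chrom,
        left_breakpoint=lbp,
        right_breakpoint=rbp,
        left_precision=lprec,
        right_precision=rprec,
        left_support=(count(left, "discordant_pair"), count(left, "split_read")),
        right_support=(count(right, "discordant_pair"), count(right, "split_read")),
        left_vector_end=_vector_end(left, vector_length),
        right_vector_end=_vector_end(right, vector_length),
        status=status,
    )


# ---------------------------------------------------------------------------
# corroboration and annotation
# ---------------------------------------------------------------------------


def support_multiplicity(
    call: InsertionLocusCall,
    vector_profile: CoverageProfile,
    genome_average_coverage: float,
    mask: Sequence[tuple[int, int]] = (),
) -> Optional[float]:
    """Vector depth over genome average: corroborates the copy-number ratio.

    Uses the mean depth of unmasked vector positions; None when the locus has
    no support or the genome average is unknown.
    """
    if call.total_support == 0 or genome_average_coverage <= 0:
        return None
    n = len(vector_profile.depth)
    unmasked = np.ones(n, dtype=bool)
    for s, e in mask:
        unmasked[max(0, s) : min(n, e)] = False
    if not unmasked.any():
        return None
    return float(vector_profile.depth[unmasked].mean()) / genome_average_coverage


def annotate_context(
    call: InsertionLocusCall, gff_rows: Sequence[dict]
) -> InsertionLocusCall:
    """Attach feature context: exon/intron/intergenic plus flanking genes."""
    rows = [r for r in gff_rows if r["seqid"] == call.chrom]
    if not rows:
        call.context = {"class": "unannotated"}
        return call
    pos = call.anchor_pos
    genes = [r for r in rows if r["type"] == "gene"]
    exons = [r for r in rows if r["type"] == "exon"]
    hit_gene = next((g for g in genes if g["start"] <= pos < g["end"]), None)
    if hit_gene is not None:
        in_exon = any(e["start"] <= pos < e["end"] for e in exons)
        call.context = {
            "class": "exon" if in_exon else "intron",
            "gene": hit_gene["attrs"].get("Name")
            or hit_gene["attrs"].get("ID", "gene"),
        }
        return call
    upstream = [g for g in genes if g["end"] <= pos]
    downstream = [g for g in genes if g["start"] > pos]
    context = {"class": "intergenic"}
    if upstream:
        g = max(upstream, key=lambda g: g["end"])
        context["upstream_gene"] = g["attrs"].get("Name") or g["attrs"].get("ID")
        context["upstream_distance"] = pos - g["end"]
    if downstream:
        g = min(downstream, key=lambda g: g["start"])
        context["downstream_gene"] = g["attrs"].get("Name") or g["attrs"].get("ID")
        context["downstream_distance"] = g["start"] - pos
    call.context = context
    return call


__all__ = [
    "JunctionEvidence", "InsertionLocusCall",
    "extract_junction_pairs", "extract_split_reads", "extract_clipped_ends",
    "cluster_evidence",
    "support_multiplicity", "annotate_context",
    "DEFAULT_WINDOW", "DEFAULT_MIN_SUPPORT", "DEFAULT_MIN_CLIP",
]
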