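"""Orchestration: simulate -> map -> profile -> detect -> characterize.

``characterize`` is the in-memory core; ``run_characterize`` wraps it with
file I/O, per-stage artifacts and logging; ``run_simulate`` materializes a
preset fixture directory with a ready-made characterize config;
``verify_against_truth`` scores a report against a fixture's truth record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from vectorint import __version__
from vectorint._util import (
    DNA_ALPHABET,
    read_fasta,
    read_fastq,
    write_fasta,
    write_fastq_pair,
)
from vectorint.alignment import (
    AlignmentRecord,
    build_index,
    compute_mapping_stats,
    map_pairs,
    read_gff3,
    read_sam,
    write_gff3,
    write_sam,
)
from vectorint.coverage import (
    CoverageProfile,
    depth_profile,
    estimate_copy_number,
    feature_coverage,
    integrity_report,
    mask_shared_segments,
)
from vectorint.junctions import (
    annotate_context,
    cluster_evidence,
    extract_clipped_ends,
    extract_junction_pairs,
    extract_split_reads,
    support_multiplicity,
)
from vectorint.simulate import (
    HOUSEKEEPING_INTERVAL,
    MARKER_FEATURE,
    simulate_line,
)
from vectorint.svcalls import (
    StructuralVariantCall,
    chain_anchors,
    classify_chain,
    find_anchors,
    reconcile_breakpoints,
    scan_adjacent_deletion,
)

logger = logging.getLogger(__name__)

VECTOR_NAME = "vector"


@dataclass(frozen=True)
class Params:
    """Tunable thresholds for every stage, with documented defaults."""

    k: int = 20
    anchor_k: int = 15
    window: int = 530
    min_support: int = 3
    min_clip: int = 15
    min_depth: int = 5
    del_frac: float = 0.1
    min_del_len: int = 10_000
    insert_mean: int = 265
    max_insert: int = 2000
    breakpoint_tol: int = 5


@dataclass
class LineReport:
    """Consolidated per-line result; losslessly (de)serializable to JSON."""

    line: str
    mapping_stats: dict
    copy_number: Optional[dict]
    integrity: dict
    loci: list[dict]
    svs: list[dict]
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LineReport":
        return cls(**json.loads(text))


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _qc_reads(pairs: Sequence[tuple[str, str, str]]) -> dict:
    """Basic validity checks standing in for read QC: length and alphabet."""
    lengths = set()
    bad_alphabet = 0
    for _name, s1, s2 in pairs:
        lengths.add(len(s1))
        lengths.add(len(s2))
        if not (set(s1) <= DNA_ALPHABET and set(s2) <= DNA_ALPHABET):
            bad_alphabet += 1
    qc = {"n_pairs": len(pairs), "read_lengths": sorted(lengths),
          "pairs_with_non_acgt": bad_alphabet}
    logger.info("read QC: %s", qc)
    return qc


# ---------------------------------------------------------------------------
# in-memory characterization core
# ---------------------------------------------------------------------------


def characterize(
    reference: dict[str, str],
    vector_seq: str,
    vector_features: Sequence[tuple[str, int, int, str]],
    housekeeping: tuple[str, int, int] = HOUSEKEEPING_INTERVAL,
    marker_feature: str = MARKER_FEATURE,
    pairs: Optional[Sequence[tuple[str, str, str]]] = None,
    alignments: Optional[Sequence[AlignmentRecord]] = None,
    contigs: Sequence[tuple[str, str]] = (),
    gff_rows: Sequence[dict] = (),
    params: Params = Params(),
    line: str = "line",
) -> LineReport:
    """Run the full per-line analysis on in-memory inputs."""
    if pairs is None and alignments is None:
        raise ValueError("need reads or alignments")
    targets = dict(reference)
    if VECTOR_NAME in targets:
        raise ValueError(f"reference may not contain a target named {VECTOR_NAME!r}")
    targets[VECTOR_NAME] = vector_seq
    index = build_index(targets, k=params.k)

    # --- stage: mapping
    if alignments is None:
        _qc_reads(pairs)
        alignments = map_pairs(pairs, index, max_insert=params.max_insert)
        n_raw_pairs = len(pairs)
    else:
        n_raw_pairs = max(1, sum(1 for r in alignments if r.read_index == 1))
    ref_length = sum(len(s) for s in reference.values())
    stats = compute_mapping_stats(
        alignments, reference_length_bp=ref_length, total_raw_reads=n_raw_pairs
    )
    logger.info("mapping: %d records, coverage %.1fx",
                len(alignments), stats.average_coverage)

    # --- stage: coverage profiles and masking
    profiles = {
        name: depth_profile(alignments, name, len(seq))
        for name, seq in targets.items()
    }
    mask = mask_shared_segments(vector_seq, reference)
    integ = integrity_report(
        profiles[VECTOR_NAME], mask, vector_features, min_depth=params.min_depth
    )

    # --- stage: copy number
    marker_iv = next(
        ((s, e) for lab, s, e, _ in vector_features if lab == marker_feature), None
    )
    copy_number = None
    if marker_iv and integ.vector_present:
        marker_stat = feature_coverage(
            profiles[VECTOR_NAME], marker_iv, label=marker_feature
        )
        hk_chrom, hk_s, hk_e = housekeeping
        hk_stat = feature_coverage(
            profiles[hk_chrom], (hk_s, hk_e), label="housekeeping"
        )
        if hk_stat.average_coverage > 0:
            copy_number = estimate_copy_number(marker_stat, hk_stat).report()

    # --- stage: junction detection
    pair_ev = extract_junction_pairs(
        alignments, VECTOR_NAME, mask, insert_size_hint=params.insert_mean
    )
    split_ev = extract_split_reads(
        alignments, index, VECTOR_NAME, mask, min_clip=params.min_clip
    )
    clip_hints = extract_clipped_ends(alignments, VECTOR_NAME,
                                      min_clip=params.min_clip)
    logger.info("junction evidence: %d pairs, %d splits, %d clip hints",
                len(pair_ev), len(split_ev), len(clip_hints))
    calls = cluster_evidence(
        pair_ev + split_ev, vector_length=len(vector_seq),
        window=params.window, min_support=params.min_support,
        clip_hints=clip_hints,
    )
    chrom_medians = [profiles[c].median for c in reference]
    genome_baseline = float(np.median(chrom_medians)) if chrom_medians else 0.0
    for call in calls:
        annotate_context(call, gff_rows)
        mult = support_multiplicity(
            call, profiles[VECTOR_NAME], genome_baseline, mask
        )
        call.context["support_multiplicity"] = (
            round(mult, 2) if mult is not None else None
        )

    # --- stage: SV characterization
    svs: list[StructuralVariantCall] = []
    for call in calls:
        sv = reconcile_breakpoints(call)
        if sv is not None:
            svs.append(sv)
        adj = scan_adjacent_deletion(
            profiles[call.chrom], call, del_frac=params.del_frac,
            min_del_len=params.min_del_len, baseline=genome_baseline,
        )
        if adj is not None:
            svs.append(adj)
    for cname, cseq in contigs:
        anchors = find_anchors(cseq, targets, k=params.anchor_k)
        chain = chain_anchors(anchors)
        chain_calls = classify_chain(
            chain, cseq, VECTOR_NAME, len(vector_seq),
            vector_seq=vector_seq, reference=reference,
        )
        for sv in chain_calls:
            sv.info.setdefault("contig", cname)
        svs.extend(chain_calls)
    svs = _dedupe_svs(svs, tol=params.breakpoint_tol)

    return LineReport(
        line=line,
        mapping_stats=stats.report(),
        copy_number=copy_number,
        integrity=integ.report(),
        loci=[c.to_json_dict() for c in calls],
        svs=[s.to_json_dict() for s in svs],
        provenance={"version": __version__},
    )


def _dedupe_svs(svs: list[StructuralVariantCall], tol: int = 5
                ) -> list[StructuralVariantCall]:
    """Merge junction-read and contig views of the same event.

    Junction-read calls carry base-exact breakpoints, so they win; the merged
    record notes both provenances.
    """
    geometry = {"blunt_junction", "target_site_duplication", "target_deletion"}

    def same_event(a: StructuralVariantCall, b: StructuralVariantCall) -> bool:
        if abs(a.length - b.length) > tol:
            return False
        # within micro-homology tolerance, blunt / tiny TSD / tiny deletion
        # are one description of the same host-side junction
        return a.type == b.type or (a.type in geometry and b.type in geometry)

    out: list[StructuralVariantCall] = []
    for sv in sorted(svs, key=lambda s: 0 if s.provenance == "junction_reads" else 1):
        dup = next((o for o in out if same_event(o, sv)), None)
        if dup is not None:
            dup.info["provenance_also"] = sv.provenance
            continue
        out.append(sv)
    return out


# ---------------------------------------------------------------------------
# file-based runs
# ---------------------------------------------------------------------------


def _read_features_bed(path: str) -> list[tuple[str, int, int, str]]:
    feats = []
    with open(path) as fh:
        for row in fh:
            if not row.strip() or row.startswith("#"):
                continue
            parts = row.split("\t")
            feats.append((parts[3], int(parts[1]), int(parts[2]),
                          parts[5].strip() if len(parts) > 5 else "+"))
    return feats


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def run_characterize(config: dict, out_dir: Optional[str] = None) -> LineReport:
    """File-based pipeline run; writes per-stage artifacts under ``out_dir``."""
    base = os.path.dirname(config.get("__path__", "")) or "."
    path = lambda key: os.path.join(base, config[key])  # noqa: E731
    for key in ("reference", "vector", "vector_features"):
        if key not in config:
            raise ValueError(f"config missing {key!r}")
        if not os.path.exists(path(key)):
            raise FileNotFoundError(path(key))
    reference = dict(read_fasta(path("reference")))
    vector_seq = dict(read_fasta(path("vector")))
    vector_seq = next(iter(vector_seq.values()))
    features = _read_features_bed(path("vector_features"))
    params = Params(**config.get("params", {}))
    pairs = alignments = None
    if config.get("sam"):
        alignments = read_sam(path("sam")).records
    elif config.get("reads1") and config.get("reads2"):
        r1 = read_fastq(path("reads1"))
        r2 = read_fastq(path("reads2"))
        if len(r1) != len(r2):
            raise ValueError("mate files differ in read count")
        pairs = [
            (n1.rsplit("/", 1)[0], s1, s2)
            for (n1, s1), (_n2, s2) in zip(r1, r2)
        ]
    else:
        raise ValueError("config needs either 'sam' or 'reads1'+'reads2'")
    contigs = read_fasta(path("contigs")) if config.get("contigs") else []
    gff_rows = read_gff3(path("gff")) if config.get("gff") else []
    hk = tuple(config.get("housekeeping", HOUSEKEEPING_INTERVAL))
    report = characterize(
        reference=reference,
        vector_seq=vector_seq,
        vector_features=features,
        housekeeping=hk,
        marker_feature=config.get("marker_feature", MARKER_FEATURE),
        pairs=pairs,
        alignments=alignments,
        contigs=contigs,
        gff_rows=gff_rows,
        params=params,
        line=config.get("line", "line"),
    )
    cfg_for_hash = {k: v for k, v in config.items() if not k.startswith("__")}
    report.provenance["config_hash"] = config_hash(cfg_for_hash)
    report.provenance["seed"] = config.get("seed")
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        _write_artifacts(report, out_dir)
    return report


def _write_artifacts(report: LineReport, out_dir: str) -> None:
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    with open(os.path.join(out_dir, "loci.bed"), "w") as fh:
        for call in report.loci:
            lo = min(b for b in (call["left_breakpoint"], call["right_breakpoint"])
                     if b is not None)
            hi = max(b for b in (call["left_breakpoint"], call["right_breakpoint"])
                     if b is not None)
            support = sum(call["left_support"]) + sum(call["right_support"])
            fh.write(f"{call['chrom']}\t{lo}\t{max(hi, lo + 1)}\t"
                     f"insertion_{call['status']}\t{support}\n")
    with open(os.path.join(out_dir, "svs.tsv"), "w") as fh:
        fh.write("CHROM\tPOS\tEND\tSVTYPE\tSVLEN\tINFO\n")
        for sv in report.svs:
            info = ";".join(
                f"{k}={v}" for k, v in sv.items()
                if k not in ("type", "target", "start", "end", "length")
                and v is not None
            )
            fh.write(f"{sv['target']}\t{sv['start']}\t{sv['end']}\t"
                     f"{sv['type']}\t{sv['length']}\t{info}\n")


def run_simulate(
    preset: str,
    out_dir: str,
    seed: int = 0,
    depth: float = 100.0,
    error_rate: float = 0.0,
    force: bool = False,
) -> dict:
    """Write a full fixture directory plus a ready-made characterize config."""
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    sim = simulate_line(preset, seed=seed, depth=depth, error_rate=error_rate)
    write_fasta(sim.reference.sequences, os.path.join(out_dir, "reference.fasta"))
    write_fasta([(VECTOR_NAME, sim.vector.sequence)],
                os.path.join(out_dir, "vector.fasta"))
    with open(os.path.join(out_dir, "vector_features.bed"), "w") as fh:
        for label, s, e, strand in sim.vector.features:
            fh.write(f"{VECTOR_NAME}\t{s}\t{e}\t{label}\t0\t{strand}\n")
    write_fastq_pair(sim.reads, os.path.join(out_dir, "reads_1.fastq"),
                     os.path.join(out_dir, "reads_2.fastq"))
    write_gff3(sim.gff, os.path.join(out_dir, "annotation.gff3"))
    if sim.contig is not None:
        write_fasta([sim.contig], os.path.join(out_dir, "contigs.fasta"))
    if sim.truth is not None:
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(sim.truth.to_json_dict(), fh, indent=2)
        with open(os.path.join(out_dir, "breakpoints.bed"), "w") as fh:
            t = sim.truth
            lo, hi = sorted((t.left_breakpoint, t.right_breakpoint))
            fh.write(f"{t.chrom}\t{lo}\t{max(hi, lo + 1)}\ttrue_insertion\n")
    config = {
        "line": preset,
        "seed": seed,
        "reference": "reference.fasta",
        "vector": "vector.fasta",
        "vector_features": "vector_features.bed",
        "reads1": "reads_1.fastq",
        "reads2": "reads_2.fastq",
        "gff": "annotation.gff3",
        "housekeeping": list(HOUSEKEEPING_INTERVAL),
        "marker_feature": MARKER_FEATURE,
        "params": {"insert_mean": int(sim.read_config.insert_mean)},
    }
    if sim.contig is not None:
        config["contigs"] = "contigs.fasta"
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config


# ---------------------------------------------------------------------------
# scoring against truth
# ---------------------------------------------------------------------------

_ORIGIN_EQUIV = {
    "unknown": "unknown_origin",
    "external": "unknown_origin",
}


def _origin_matches(truth_origin: str, called_origin: Optional[str]) -> bool:
    if called_origin is None:
        return True
    if truth_origin.startswith("vector-duplicate"):
        return called_origin == "vector_duplicate"
    return _ORIGIN_EQUIV.get(truth_origin, truth_origin) == called_origin


def verify_against_truth(
    report: LineReport | dict,
    truth: dict,
    tol_bp: int = 5,
    len_tol: int = 5,
    del_tol: int = 1000,
) -> dict:
    """Score a line report against a fixture truth record.

    Returns a scorecard with locus position errors, copy-number error and an
    SV type/length confusion table; ``ok`` is True only when every check
    passes at the stated tolerances.
    """
    rep = asdict(report) if isinstance(report, LineReport) else dict(report)
    if rep.get("line") != truth.get("line"):
        raise ValueError(
            f"fixture mismatch: report {rep.get('line')!r} vs truth {truth.get('line')!r}"
        )
    card: dict = {"line": rep.get("line"), "ok": True, "failures": []}

    def fail(msg: str) -> None:
        card["ok"] = False
        card["failures"].append(msg)

    # locus
    loci = rep.get("loci", [])
    card["n_loci"] = len(loci)
    if len(loci) != 1:
        fail(f"expected exactly 1 locus, found {len(loci)}")
    else:
        call = loci[0]
        if call["chrom"] != truth["chrom"]:
            fail(f"locus chromosome {call['chrom']} != {truth['chrom']}")
        lerr = (abs(call["left_breakpoint"] - truth["left_breakpoint"])
                if call["left_breakpoint"] is not None else None)
        card["left_breakpoint_error"] = lerr
        if lerr is None or lerr > tol_bp:
            fail(f"left breakpoint error {lerr}")
        if truth.get("right_flank_absent"):
            card["right_breakpoint_error"] = None
            if call["status"] != "left_only":
                fail(f"expected left_only status, got {call['status']}")
        else:
            rerr = (abs(call["right_breakpoint"] - truth["right_breakpoint"])
                    if call["right_breakpoint"] is not None else None)
            card["right_breakpoint_error"] = rerr
            if rerr is None or rerr > tol_bp:
                fail(f"right breakpoint error {rerr}")

    # copy number
    cn = rep.get("copy_number")
    card["copy_number_call"] = cn["integer_call"] if cn else None
    if cn is None or cn["integer_call"] != truth["copies"]:
        fail(
            f"copy number {cn['integer_call'] if cn else None} != {truth['copies']}"
        )

    # SV set
    confusion = []
    called = list(rep.get("svs", []))
    for event in truth.get("events", []):
        etype = event["type"]
        if etype == "blunt_junction" and truth.get("right_flank_absent"):
            continue  # one-sided loci cannot resolve the host-side join
        tol = del_tol if etype == "adjacent_large_deletion" else len_tol
        # junctional micro-homology makes a blunt join indistinguishable from
        # a TSD/deletion of a couple of bases, in either direction
        equiv_types = {etype}
        if etype == "blunt_junction":
            equiv_types |= {"target_site_duplication", "target_deletion"}
        match = None
        for sv in called:
            if sv["type"] not in equiv_types:
                continue
            if abs(sv["length"] - event["length"]) > tol:
                continue
            if etype == "tandem_multicopy":
                if sv.get("copies") != event.get("copies"):
                    continue
                if sv.get("orientations") != event.get("orientations"):
                    continue
            if etype == "filler_insertion" and not _origin_matches(
                event.get("origin", "unknown"), sv.get("origin")
            ):
                continue
            match = sv
            break
        if match is None:
            confusion.append(
                {"type": etype, "length": event["length"],
                 "expected": 1, "found": 0}
            )
            fail(f"missing {etype} of length {event['length']}")
        else:
            called.remove(match)
    card["sv_confusion"] = confusion
    card["unmatched_calls"] = [
        {"type": sv["type"], "length": sv["length"]} for sv in called
        if sv["type"] not in ("blunt_junction",)
    ]
    if card["unmatched_calls"]:
        fail(f"extra calls: {card['unmatched_calls']}")
    return card


__all__ = [
    "Params", "LineReport", "characterize", "run_characterize",
    "run_simulate", "verify_against_truth", "config_hash", "load_config",
    "VECTOR_NAME",
]
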