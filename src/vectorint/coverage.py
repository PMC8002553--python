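"""Depth profiles, feature coverage, copy-number ratios and vector integrity.

The copy-number estimator is the coverage-ratio method: average depth of the
vector selectable marker over average depth of a single-copy housekeeping
gene, computed on unrounded values and rounded only for the report. Vector
integrity is profiled after masking vector intervals shared with the host
genome, since those recruit genomic reads even in untransformed lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from vectorint._util import merge_intervals, revcomp, round_half_up
from vectorint.alignment import AlignmentRecord
from vectorint.simulate import VectorTemplate

MIN_COVERED_DEPTH = 5      # a base counts as covered at >= this depth
MASK_MIN_LEN = 100         # minimal reported shared-segment length
MASK_K = 31                # exact anchor size for homology masking


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Per-base aligned depth on one target."""

    target: str
    depth: np.ndarray  # int array, length = target length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depth must be >= 0 everywhere")

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.depth)) if self.depth.size else 0.0

    @property
    def total_aligned_bases(self) -> int:
        return int(self.depth.sum())

    def window_means(self, window: int) -> list[tuple[int, float]]:
        """(window_start, mean depth) summary rows."""
        out = []
        for s in range(0, len(self.depth), window):
            out.append((s, float(self.depth[s : s + window].mean())))
        return out


@dataclass(frozen=True)
class CoverageStat:
    """Feature-level coverage: C = L / G."""

    label: str
    feature_length_bp: int                # G
    total_mapped_length_bp: int           # L

    def __post_init__(self) -> None:
        if self.feature_length_bp <= 0:
            raise ValueError("feature length must be > 0")

    @property
    def average_coverage(self) -> float:
        return self.total_mapped_length_bp / self.feature_length_bp

    def report(self) -> dict:
        return {
            "label": self.label,
            "feature_length_bp": self.feature_length_bp,
            "total_mapped_length_bp": self.total_mapped_length_bp,
            "average_coverage": int(round_half_up(self.average_coverage)),
        }


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Marker/housekeeping coverage ratio and its integerized call."""

    marker: CoverageStat
    housekeeping: CoverageStat

    @property
    def ratio(self) -> float:
        return self.marker.average_coverage / self.housekeeping.average_coverage

    @property
    def reported(self) -> float:
        return round_half_up(self.ratio, 2)

    @property
    def integer_call(self) -> int:
        return int(round_half_up(self.ratio))

    @property
    def off_integer(self) -> bool:
        """Flagged when the ratio sits > 0.25 from the nearest integer."""
        return abs(self.ratio - round(self.ratio)) > 0.25

    def report(self) -> dict:
        return {
            "marker": self.marker.report(),
            "housekeeping": self.housekeeping.report(),
            "copy_number": self.reported,
            "integer_call": self.integer_call,
            "off_integer": self.off_integer,
        }


@dataclass
class IntegrityReport:
    """Coverage-based vector integrity after homology masking."""

    masked_intervals: list[tuple[int, int]]
    covered_fraction: float               # of unmasked vector length
    uncovered_segments: list[tuple[int, int]]
    feature_verdicts: dict[str, str]      # intact | partially deleted | deleted | masked
    vector_present: bool

    def report(self) -> dict:
        return {
            "masked_intervals": self.masked_intervals,
            "covered_fraction": round_half_up(self.covered_fraction, 4),
            "uncovered_segments": self.uncovered_segments,
            "feature_verdicts": self.feature_verdicts,
            "vector_present": self.vector_present,
        }


# ---------------------------------------------------------------------------
# depth and feature coverage
# ---------------------------------------------------------------------------


def depth_profile(
    alignments: Sequence[AlignmentRecord],
    target: str,
    target_length: int,
) -> CoverageProfile:
    """Per-base depth of uniquely mapped, non-clipped (M) bases on ``target``."""
    if target_length <= 0:
        raise ValueError(f"unknown or empty target {target!r}")
    diff = np.zeros(target_length + 1, dtype=np.int64)
    seen = False
    for r in alignments:
        if r.status != "unique" or r.target != target:
            continue
        seen = seen or True
        for s, e in r.aligned_blocks():
            s = max(0, s)
            e = min(target_length, e)
            if e > s:
                diff[s] += 1
                diff[e] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(target=target, depth=depth)


def feature_coverage(
    source: CoverageProfile | Sequence[AlignmentRecord],
    feature: tuple[int, int],
    label: str = "feature",
    target: Optional[str] = None,
    target_length: Optional[int] = None,
    total_mapped_length_bp: Optional[int] = None,
) -> CoverageStat:
    """Average coverage C = L/G over a feature interval.

    L is the number of aligned bases falling inside the feature (overlap
    bases, not whole-read lengths), which keeps the marker/housekeeping ratio
    free of read-overhang bias on short features. Printed tables can be
    reproduced by passing ``total_mapped_length_bp`` directly.
    """
    start, end = feature
    if end <= start:
        raise ValueError("empty feature")
    if total_mapped_length_bp is not None:
        return CoverageStat(label, end - start, int(total_mapped_length_bp))
    if isinstance(source, CoverageProfile):
        profile = source
    else:
        if target is None or target_length is None:
            raise ValueError("need target and target_length with raw alignments")
        profile = depth_profile(source, target, target_length)
    L = int(profile.depth[start:end].sum())
    return CoverageStat(label, end - start, L)


def estimate_copy_number(
    marker: CoverageStat, housekeeping: CoverageStat
) -> CopyNumberEstimate:
    """Coverage-ratio copy number; zero housekeeping coverage is rejected."""
    if housekeeping.average_coverage <= 0:
        raise ValueError(
            "housekeeping gene has zero coverage: bad reference choice"
        )
    return CopyNumberEstimate(marker=marker, housekeeping=housekeeping)


def replicon_copy_ratio(
    profiles: dict[str, CoverageProfile],
    nuclear_targets: Sequence[str],
) -> dict[str, float]:
    """Per-target mean depth relative to the median of nuclear target means."""
    nuclear = [t for t in nuclear_targets if t in profiles]
    if not nuclear:
        raise ValueError("at least one nuclear target must be designated")
    baseline = float(np.median([profiles[t].mean for t in nuclear]))
    if baseline == 0:
        raise ValueError("nuclear targets have zero coverage")
    return {name: p.mean / baseline for name, p in profiles.items()}


# ---------------------------------------------------------------------------
# homology masking and integrity
# ---------------------------------------------------------------------------


def mask_shared_segments(
    vector: VectorTemplate | str,
    reference: Sequence[tuple[str, str]] | dict[str, str],
    k: int = MASK_K,
    min_len: int = MASK_MIN_LEN,
    max_gap: int = 10,
) -> list[tuple[int, int]]:
    """Vector intervals sharing long (near-)exact stretches with the reference.

    Exact ``k``-mer anchors against both reference strands are merged (small
    gaps bridged, tolerating isolated substitutions) and intervals >=
    ``min_len`` are reported. On simulated vectors this recovers declared
    host-derived segments exactly.
    """
    vseq = vector.sequence if isinstance(vector, VectorTemplate) else vector
    ref_seqs = reference.values() if isinstance(reference, dict) else (
        s for _, s in reference
    )
    ref_kmers: set[str] = set()
    for seq in ref_seqs:
        for i in range(len(seq) - k + 1):
            ref_kmers.add(seq[i : i + k])
    hits = []
    for i in range(len(vseq) - k + 1):
        w = vseq[i : i + k]
        if w in ref_kmers or revcomp(w) in ref_kmers:
            hits.append((i, i + k))
    merged = merge_intervals(hits, max_gap=max_gap)
    return [(s, e) for s, e in merged if e - s >= min_len]


def integrity_report(
    profile: CoverageProfile,
    mask: Sequence[tuple[int, int]],
    features: Sequence[tuple[str, int, int, str]],
    min_depth: int = MIN_COVERED_DEPTH,
    present_threshold: float = 0.02,
) -> IntegrityReport:
    """Covered fraction and per-feature verdicts over the unmasked vector.

    A base is covered at depth >= ``min_depth``. A feature is intact when
    >= 99% of its unmasked length is covered, deleted when <= 1%, otherwise
    partially deleted; fully masked features are reported as 'masked'.
    """
    n = len(profile.depth)
    masked = np.zeros(n, dtype=bool)
    for s, e in mask:
        masked[max(0, s) : min(n, e)] = True
    covered = profile.depth >= min_depth
    unmasked = ~masked
    unmasked_len = int(unmasked.sum())
    covered_fraction = (
        float(covered[unmasked].sum()) / unmasked_len if unmasked_len else 0.0
    )
    # uncovered unmasked runs
    bad = unmasked & ~covered
    uncovered: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    for s, e in zip(idx[0::2], idx[1::2]):
        uncovered.append((int(s), int(e)))
    uncovered = merge_intervals(uncovered, max_gap=0)

    verdicts: dict[str, str] = {}
    for label, fs, fe, _strand in features:
        fu = unmasked[fs:fe]
        flen = int(fu.sum())
        if flen == 0:
            verdicts[label] = "masked"
            continue
        frac = float(covered[fs:fe][fu].sum()) / flen
        if frac >= 0.99:
            verdicts[label] = "intact"
        elif frac <= 0.01:
            verdicts[label] = "deleted"
        else:
            verdicts[label] = "partially deleted"

    return IntegrityReport(
        masked_intervals=[tuple(iv) for iv in mask],
        covered_fraction=covered_fraction,
        uncovered_segments=uncovered,
        feature_verdicts=verdicts,
        vector_present=covered_fraction > present_threshold,
    )


__all__ = [
    "CoverageProfile", "CoverageStat", "CopyNumberEstimate", "IntegrityReport",
    "depth_profile", "feature_coverage", "estimate_copy_number",
    "replicon_copy_ratio", "mask_shared_segments", "integrity_report",
    "MIN_COVERED_DEPTH",
]
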