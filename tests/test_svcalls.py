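"""Tests for breakpoint reconciliation, filler origin, anchors and chains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vectorint._util import revcomp
from vectorint.coverage import CoverageProfile
from vectorint.junctions import InsertionLocusCall
from vectorint.simulate import (
    InsertionEventSpec,
    apply_insertion,
    emit_locus_contig,
    generate_reference,
    simulate_line,
)
from vectorint.svcalls import (
    chain_anchors,
    chain_exhaustive,
    chain_weight,
    classify_chain,
    classify_filler,
    find_anchors,
    reconcile_breakpoints,
    scan_adjacent_deletion,
)


def _call(left, right, lprec="exact", rprec="exact", status="both_ends"):
    return InsertionLocusCall(
        chrom="chr01", left_breakpoint=left, right_breakpoint=right,
        left_precision=lprec, right_precision=rprec, status=status,
    )


class TestReconcileBreakpoints:
    def test_target_deletion(self):
        sv = reconcile_breakpoints(_call(1000, 1206))
        assert (sv.type, sv.length) == ("target_deletion", 206)
        assert (sv.start, sv.end) == (1000, 1206)

    def test_target_site_duplication(self):
        sv = reconcile_breakpoints(_call(5518, 5000))
        assert (sv.type, sv.length) == ("target_site_duplication", 518)

    def test_blunt_junction(self):
        sv = reconcile_breakpoints(_call(4242, 4242))
        assert (sv.type, sv.length) == ("blunt_junction", 0)

    def test_interval_precision_unresolved(self):
        assert reconcile_breakpoints(_call(100, 200, rprec="interval")) is None

    def test_one_sided_call_unresolved(self):
        assert reconcile_breakpoints(
            _call(100, None, rprec="absent", status="left_only")
        ) is None

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=1, max_value=600))
    def test_tsd_sign_convention_self_inverse(self, x):
        """A simulated TSD of length x always reads back as +x, never -x."""
        ref = generate_reference(1, [3000], gc=0.5, seed=1)
        vec_seq = generate_reference(1, [1500], gc=0.5, seed=2).get("chr01")
        from vectorint.simulate import VectorTemplate

        vec = VectorTemplate(sequence=vec_seq, features=())
        event = InsertionEventSpec(target=("chr01", 1500), tsd_bp=x)
        _, truth = apply_insertion(ref, vec, event)
        sv = reconcile_breakpoints(
            _call(truth.left_breakpoint, truth.right_breakpoint)
        )
        assert sv.type == "target_site_duplication"
        assert sv.length == x


@pytest.fixture(scope="module")
def filler_setup():
    ref = generate_reference(1, [5000], gc=0.5, seed=81)
    vector = generate_reference(1, [2000], gc=0.5, seed=82).get("chr01")
    return ref, vector


@pytest.fixture(scope="module")
def anchor_target():
    return generate_reference(1, [3000], gc=0.5, seed=91).get("chr01")


class TestClassifyFiller:
    @pytest.fixture()
    def setup(self, filler_setup):
        return filler_setup

    def test_vector_duplicate_with_interval(self, setup):
        ref, vector = setup
        fc = classify_filler(vector[1481:1543], vector, ref.as_dict())
        assert fc.verdict == "vector_duplicate"
        assert fc.source == ("vector", 1481, 1543)
        assert fc.identity == 1.0

    def test_unknown_origin_for_kmer_free_sequence(self, setup):
        ref, vector = setup
        from vectorint.simulate import VectorTemplate, make_filler

        vt = VectorTemplate(sequence=vector, features=())
        rng = np.random.default_rng(3)
        filler = make_filler(83, ref, vt, rng)
        fc = classify_filler(filler, vector, ref.as_dict())
        assert fc.verdict == "unknown_origin"

    def test_genome_derived(self, setup):
        ref, vector = setup
        fc = classify_filler(ref.get("chr01")[400:460], vector, ref.as_dict())
        assert fc.verdict == "genome_derived"
        assert fc.source == ("chr01", 400, 460)

    def test_reverse_strand_match(self, setup):
        ref, vector = setup
        fc = classify_filler(revcomp(vector[100:170]), vector, ref.as_dict())
        assert fc.verdict == "vector_duplicate"

    def test_micro_insertion_below_threshold(self, setup):
        ref, vector = setup
        assert classify_filler("ACGTACG", vector, ref.as_dict()).verdict == (
            "micro-insertion"
        )


class TestFindAnchors:
    @pytest.fixture()
    def target(self, anchor_target):
        return anchor_target

    def test_identity_contig_single_forward_anchor(self, target):
        anchors = find_anchors(target, {"t": target})
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.contig_start, a.contig_end, a.orientation) == (0, 3000, "+")
        assert (a.target_start, a.target_end) == (0, 3000)

    def test_revcomp_contig_single_minus_anchor(self, target):
        anchors = find_anchors(revcomp(target), {"t": target})
        assert len(anchors) == 1
        assert anchors[0].orientation == "-"
        assert (anchors[0].target_start, anchors[0].target_end) == (0, 3000)

    def test_inversion_breaks_anchors_inner_minus(self, target):
        contig = target[:1000] + revcomp(target[1000:1171]) + target[1171:]
        anchors = find_anchors(contig, {"t": target})
        minus = [a for a in anchors if a.orientation == "-"]
        assert len(minus) == 1
        assert (minus[0].target_start, minus[0].target_end) == (1000, 1171)
        plus_spans = sorted(
            (a.target_start, a.target_end)
            for a in anchors if a.orientation == "+"
        )
        assert plus_spans[0][0] == 0 and plus_spans[-1][1] == 3000

    def test_min_len_filter(self, target):
        other = generate_reference(1, [1000], gc=0.5, seed=92).get("chr01")
        contig = other[:500] + target[100:140] + other[500:]
        assert find_anchors(contig, {"t": target}, min_len=50) == []
        found = find_anchors(contig, {"t": target}, min_len=30)
        assert any(a.length == 40 for a in found)

    def test_k_floor(self, target):
        with pytest.raises(ValueError):
            find_anchors(target, {"t": target}, k=10)


class TestChainAnchors:
    def test_single_anchor_identity(self, ):
        target = generate_reference(1, [2000], gc=0.5, seed=93).get("chr01")
        anchors = find_anchors(target, {"t": target})
        chain = chain_anchors(anchors)
        assert len(chain) == 1
        assert chain.weight == 2000

    def test_empty_input_empty_chain(self):
        chain = chain_anchors([])
        assert chain.blocks == [] and chain.weight == 0.0

    def test_dp_matches_exhaustive_on_random_anchor_sets(self):
        from vectorint.svcalls import Anchor

        rng = np.random.default_rng(17)
        for _trial in range(25):
            anchors = []
            for _ in range(int(rng.integers(2, 11))):
                cs = int(rng.integers(0, 4500))
                length = int(rng.integers(30, 400))
                ts = int(rng.integers(0, 5000))
                anchors.append(Anchor(cs, cs + length, "t", ts, ts + length,
                                      "+" if rng.random() < 0.5 else "-"))
            dp = chain_anchors(anchors)
            brute = chain_exhaustive(anchors)
            assert dp.weight == pytest.approx(brute.weight)

    def test_dp_matches_exhaustive_on_real_contig(self):
        """Chain optimality oracle on an actual small locus contig."""
        sim = simulate_line("T6", seed=9, depth=1)
        _, contig = emit_locus_contig(sim.truth, flank_bp=500)
        contig = contig[:5000]
        targets = sim.reference.as_dict()
        targets["vector"] = sim.vector.sequence
        anchors = find_anchors(contig, targets)
        # drop contained duplicates to keep brute force tractable
        assert len(anchors) <= 14
        dp = chain_anchors(anchors)
        brute = chain_exhaustive(anchors)
        assert dp.weight == pytest.approx(brute.weight)
        assert chain_weight(dp.blocks) == pytest.approx(dp.weight)


def _chain_calls(sim, flank=2000):
    _, contig = emit_locus_contig(sim.truth, flank_bp=flank)
    targets = sim.reference.as_dict()
    targets["vector"] = sim.vector.sequence
    anchors = find_anchors(contig, targets)
    chain = chain_anchors(anchors)
    return classify_chain(
        chain, contig, "vector", len(sim.vector),
        vector_seq=sim.vector.sequence, reference=sim.reference.as_dict(),
    )


class TestClassifyChain:
    """Taxonomy completeness on error-free contigs, per preset.

    Lengths carry a small slack because junctional micro-homology legitimately
    shifts maximal-exact-match boundaries by a base or two.
    """

    def _lengths(self, calls, svtype):
        return sorted(c.length for c in calls if c.type == svtype)

    def _assert_close(self, got, expected, tol=3):
        assert len(got) == len(expected)
        for g, e in zip(got, sorted(expected)):
            assert abs(g - e) <= tol

    def test_t3_taxonomy(self):
        calls = _chain_calls(simulate_line("T3", seed=10, depth=1))
        self._assert_close(
            self._lengths(calls, "target_site_duplication"), [518])
        fillers = [c for c in calls if c.type == "filler_insertion"]
        self._assert_close(sorted(f.length for f in fillers), [62, 83])
        by_origin = {f.origin for f in fillers}
        assert by_origin == {"unknown_origin", "vector_duplicate"}

    def test_t6_taxonomy(self):
        calls = _chain_calls(simulate_line("T6", seed=10, depth=1))
        self._assert_close(self._lengths(calls, "target_deletion"), [206])
        self._assert_close(self._lengths(calls, "internal_inversion"), [171])
        self._assert_close(self._lengths(calls, "filler_insertion"), [64])

    def test_t12_taxonomy(self):
        calls = _chain_calls(simulate_line("T12", seed=10, depth=1))
        tandem = [c for c in calls if c.type == "tandem_multicopy"]
        assert len(tandem) == 1
        assert tandem[0].copies == 4
        assert tandem[0].orientations == ["+", "+", "-", "+"]

    def test_t14_taxonomy(self):
        calls = _chain_calls(simulate_line("T14", seed=10, depth=1))
        self._assert_close(self._lengths(calls, "inverted_duplication"), [90])
        # right flank is gone: no host-side junction call is possible
        assert self._lengths(calls, "target_site_duplication") == []

    def test_t16_taxonomy(self):
        calls = _chain_calls(simulate_line("T16", seed=10, depth=1))
        self._assert_close(self._lengths(calls, "target_deletion"), [10])
        self._assert_close(self._lengths(calls, "filler_insertion"), [55])

    def test_identity_chain_empty_calls(self):
        target = generate_reference(1, [4000], gc=0.5, seed=94).get("chr01")
        anchors = find_anchors(target[500:3500], {"chr01": target})
        chain = chain_anchors(anchors)
        calls = classify_chain(chain, target[500:3500], "vector", 6000)
        assert calls == []

    def test_vector_truncation_detected(self):
        sim = simulate_line(
            "custom", seed=11, depth=1,
            event=InsertionEventSpec(target=("chr03", 10000),
                                     left_truncation_bp=900),
        )
        calls = _chain_calls(sim)
        trunc = [c for c in calls if c.type == "vector_truncation"]
        assert len(trunc) == 1
        assert abs(trunc[0].length - 900) <= 3
        assert trunc[0].info["side"] == "5p"


class TestAdjacentDeletionScan:
    def _locus(self, chrom, left, right=None):
        return InsertionLocusCall(
            chrom=chrom, left_breakpoint=left, right_breakpoint=right,
            left_precision="exact",
            right_precision="exact" if right is not None else "absent",
            status="both_ends" if right is not None else "left_only",
        )

    def test_t14_deletion_recovered_within_one_window(self):
        depth = np.full(150_000, 100, dtype=int)
        depth[52_000:] = 0
        profile = CoverageProfile("chr03", depth)
        sv = scan_adjacent_deletion(profile, self._locus("chr03", 52_000),
                                    baseline=100.0)
        assert sv is not None and sv.type == "adjacent_large_deletion"
        assert abs(sv.start - 52_000) <= 1000
        assert abs(sv.end - 150_000) <= 1000
        assert abs(sv.length - 98_000) <= 1000

    def test_clean_insertion_no_call(self):
        profile = CoverageProfile("chr01", np.full(30_000, 100, dtype=int))
        assert scan_adjacent_deletion(
            profile, self._locus("chr01", 15_000, 15_000), baseline=100.0
        ) is None

    def test_uniform_half_coverage_no_call(self):
        profile = CoverageProfile("chr01", np.full(30_000, 50, dtype=int))
        assert scan_adjacent_deletion(
            profile, self._locus("chr01", 15_000, 15_000), baseline=100.0
        ) is None

    def test_short_drop_below_min_length_no_call(self):
        depth = np.full(40_000, 100, dtype=int)
        depth[20_000:24_000] = 0
        profile = CoverageProfile("chr01", depth)
        assert scan_adjacent_deletion(
            profile, self._locus("chr01", 20_000, 20_000), baseline=100.0
        ) is None

    def test_wrong_chromosome_rejected(self):
        profile = CoverageProfile("chr01", np.full(20_000, 100, dtype=int))
        with pytest.raises(ValueError):
            scan_adjacent_deletion(profile, self._locus("chr02", 10_000, 10_000))

    def test_full_pipeline_t14_recovery(self, preset_runner):
        sim, report, card = preset_runner("T14", seed=8)
        dels = [s for s in report.svs if s["type"] == "adjacent_large_deletion"]
        assert len(dels) == 1
        assert abs(dels[0]["length"] - 98_000) <= 1000
        assert card["ok"]
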