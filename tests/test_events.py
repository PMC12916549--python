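import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import introcov as ic
from introcov.events import parse_translocation_name
from introcov.segmentation import SegmentCall


def segs(chrom, blocks):
    """Build tiling SegmentCalls from (start, end, state) triples."""
    return [
        SegmentCall(chrom, float(a), float(b), state,
                    1.0 if state == "present" else 0.01)
        for a, b, state in blocks
    ]


def seg_6h_s_carrier():
    # present on [0,217) and [253,281): the 6HS-carrying fusion
    return segs("6H", [(0, 217, "present"), (217, 253, "absent"),
                       (253, 281, "present"), (281, 560, "absent")])


def seg_6h_l_carrier():
    return segs("6H", [(0, 217, "absent"), (217, 253, "present"),
                       (253, 281, "absent"), (281, 560, "present")])


class TestArmStatus:
    def test_6b_short_arm_present_long_arm_absent(self, default_ref):
        s, l = ic.arm_status(
            segs("6B", [(0, 345, "present"), (345, 731, "absent")]), default_ref, "6B"
        )
        assert (s.status, s.fraction_present) == ("present", 1.0)
        assert (l.status, l.fraction_present) == ("absent", 0.0)

    def test_fully_present_chromosome_has_both_arms_present(self, toy_ref):
        s, l = ic.arm_status(segs("1W", [(0, 10, "present")]), toy_ref, "1W")
        assert s.status == l.status == "present"

    def test_inversion_shifted_6hs_carrier_is_partial(self, default_ref):
        s, _ = ic.arm_status(seg_6h_s_carrier(), default_ref, "6H")
        assert s.fraction_present == pytest.approx(217 / 253)
        assert s.status == "partial"

    def test_non_tiling_segments_rejected(self, default_ref):
        with pytest.raises(ValueError, match="segments end at"):
            ic.arm_status(segs("6B", [(0, 100, "present")]), default_ref, "6B")


def statuses_for(ref, chrom_blocks):
    out = []
    for chrom, blocks in chrom_blocks.items():
        s, l = ic.arm_status(segs(chrom, blocks), ref, chrom)
        out += [s, l]
    return out


class TestCentricFusions:
    def euploid_blocks(self, ref, skip=()):
        out = {}
        for spec in ref.chromosomes:
            if spec.name in skip:
                continue
            state = "present" if spec.subgenome == "wheat" else "absent"
            out[spec.name] = [(0, spec.length_mb, state)]
        return out

    def test_t6bs_6hl_pattern_named_with_short_arm_first(self, default_ref):
        blocks = self.euploid_blocks(default_ref, skip=("6B", "6H"))
        blocks["6B"] = [(0, 345, "present"), (345, 731, "absent")]
        blocks["6H"] = [(0, 217, "absent"), (217, 253, "present"),
                        (253, 281, "absent"), (281, 560, "present")]
        calls, _ = ic.call_centric_fusions(statuses_for(default_ref, blocks), default_ref)
        assert [c.name for c in calls] == ["T6BS.6HL"]

    def test_t4bs_4hl_pattern(self, default_ref):
        blocks = self.euploid_blocks(default_ref, skip=("4B", "4H"))
        blocks["4B"] = [(0, 317, "present"), (317, 673, "absent")]
        blocks["4H"] = [(0, 312, "absent"), (312, 647, "present")]
        calls, _ = ic.call_centric_fusions(statuses_for(default_ref, blocks), default_ref)
        assert [c.name for c in calls] == ["T4BS.4HL"]
        assert calls[0].homoeologous_group == 4

    def test_euploid_karyotype_yields_no_fusion(self, default_ref):
        calls, diagnostics = ic.call_centric_fusions(
            statuses_for(default_ref, self.euploid_blocks(default_ref)), default_ref
        )
        assert calls == [] and diagnostics == []

    def test_both_wheat_arms_absent_reported_as_whole_loss(self, default_ref):
        blocks = self.euploid_blocks(default_ref, skip=("6B",))
        blocks["6B"] = [(0, 731, "absent")]
        calls, diagnostics = ic.call_centric_fusions(
            statuses_for(default_ref, blocks), default_ref
        )
        assert calls == []
        assert any("whole_loss" in d and "6B" in d for d in diagnostics)

    @given(group=st.integers(min_value=1, max_value=7),
           wheat_genome=st.sampled_from("ABD"),
           lost=st.sampled_from("SL"))
    @settings(max_examples=30, deadline=None)
    def test_fusion_names_parse_back_to_their_arms(self, group, wheat_genome, lost):
        ref = ic.default_hybrid_reference()
        wheat = f"{group}{wheat_genome}"
        barley = f"{group}H"
        kept = "L" if lost == "S" else "S"
        blocks = self.euploid_blocks(ref, skip=(wheat, barley))
        wspec, bspec = ref.spec(wheat), ref.spec(barley)
        wc, bc = wspec.centromere_mb, bspec.centromere_mb
        blocks[wheat] = (
            [(0, wc, "absent"), (wc, wspec.length_mb, "present")] if lost == "S"
            else [(0, wc, "present"), (wc, wspec.length_mb, "absent")]
        )
        blocks[barley] = (
            [(0, bc, "present"), (bc, bspec.length_mb, "absent")] if lost == "S"
            else [(0, bc, "absent"), (bc, bspec.length_mb, "present")]
        )
        calls, _ = ic.call_centric_fusions(statuses_for(ref, blocks), ref)
        assert len(calls) == 1
        a, b = parse_translocation_name(calls[0].name)
        assert {a, b} == {f"{wheat}{kept}", f"{barley}{lost}"}
        assert a.endswith("S") and b.endswith("L")


class TestDeletions:
    def test_interstitial_deletion_on_2d(self, default_ref):
        calls = ic.call_deletions(
            segs("2D", [(0, 573, "present"), (573, 622, "absent"),
                        (622, 665, "present")]),
            default_ref, "2D",
        )
        assert len(calls) == 1
        assert (calls[0].kind, calls[0].length_mb) == ("interstitial", 49)

    def test_terminal_deletion_on_3b(self, default_ref):
        calls = ic.call_deletions(
            segs("3B", [(0, 724, "present"), (724, 851, "absent")]),
            default_ref, "3B",
        )
        assert len(calls) == 1
        assert (calls[0].kind, calls[0].length_mb) == ("terminal", 127)

    def test_fully_present_chromosome_yields_no_deletion(self, default_ref):
        assert ic.call_deletions(
            segs("2D", [(0, 665, "present")]), default_ref, "2D"
        ) == []

    def test_minority_present_chromosome_not_scanned(self, default_ref):
        # a translocation-lost arm dominates: no deletion calls here
        assert ic.call_deletions(
            segs("6B", [(0, 345, "present"), (345, 731, "absent")]),
            default_ref, "6B",
        ) == []

    def test_excluded_arm_interval_masks_the_call(self, default_ref):
        calls = ic.call_deletions(
            segs("4B", [(0, 317, "present"), (317, 673, "absent")]),
            default_ref, "4B", exclude=[(317.0, 673.0)],
        )
        assert calls == []

    def test_barley_chromosome_never_yields_deletions(self, default_ref):
        assert ic.call_deletions(
            segs("6H", [(0, 500, "present"), (500, 560, "absent")]),
            default_ref, "6H",
        ) == []

    def test_sub_threshold_absent_segment_ignored(self, default_ref):
        calls = ic.call_deletions(
            segs("2D", [(0, 300, "present"), (300, 303, "absent"),
                        (303, 665, "present")]),
            default_ref, "2D",
        )
        assert calls == []


class TestPericentricInversion:
    def test_printed_6h_present_sets_yield_64_mb_call(self, default_ref):
        call, reason = ic.infer_pericentric_inversion(
            seg_6h_s_carrier(), seg_6h_l_carrier(), default_ref, "6H"
        )
        assert call is not None
        assert (call.start_mb, call.end_mb) == (217, 281)
        assert call.length_mb == 64
        assert call.block_a == (217, 253) and call.block_b == (253, 281)
        assert call.spans_centromere

    def test_clean_fission_produces_no_call(self, default_ref):
        a = segs("6B", [(0, 345, "present"), (345, 731, "absent")])
        b = segs("6B", [(0, 345, "absent"), (345, 731, "present")])
        call, reason = ic.infer_pericentric_inversion(a, b, default_ref, "6B")
        assert call is None
        assert "fission" in reason

    def test_toy_crossover_pattern(self, toy_ref):
        a = segs("1W", [(0, 3, "present"), (3, 5, "absent"),
                        (5, 7, "present"), (7, 10, "absent")])
        b = segs("1W", [(0, 3, "absent"), (3, 5, "present"),
                        (5, 7, "absent"), (7, 10, "present")])
        call, _ = ic.infer_pericentric_inversion(a, b, toy_ref, "1W")
        assert call is not None
        assert (call.start_mb, call.end_mb) == (3, 7)

    def test_inference_symmetric_in_argument_order(self, default_ref):
        c1, _ = ic.infer_pericentric_inversion(
            seg_6h_s_carrier(), seg_6h_l_carrier(), default_ref, "6H"
        )
        c2, _ = ic.infer_pericentric_inversion(
            seg_6h_l_carrier(), seg_6h_s_carrier(), default_ref, "6H"
        )
        assert c1 == c2

    def test_overlapping_carriers_rejected(self, default_ref):
        a = segs("6H", [(0, 400, "present"), (400, 560, "absent")])
        b = segs("6H", [(0, 300, "absent"), (300, 560, "present")])
        with pytest.raises(ValueError, match="complementary"):
            ic.infer_pericentric_inversion(a, b, default_ref, "6H")

    def test_fragmented_pattern_yields_diagnostic_not_call(self, default_ref):
        a = segs("6H", [(0, 100, "present"), (100, 200, "absent"),
                        (200, 300, "present"), (300, 400, "absent"),
                        (400, 500, "present"), (500, 560, "absent")])
        b = segs("6H", [(0, 100, "absent"), (100, 200, "present"),
                        (200, 300, "absent"), (300, 400, "present"),
                        (400, 500, "absent"), (500, 560, "present")])
        call, reason = ic.infer_pericentric_inversion(a, b, default_ref, "6H")
        assert call is None
        assert "fragmented" in reason


class TestIntrogressionSummary:
    def test_t6hs_6bl_totals_245_mb_and_44_percent(self, default_ref):
        summary = ic.summarize_introgression(seg_6h_s_carrier(), default_ref, "6H")
        assert summary.total_present_mb == 245
        assert summary.percent_of_chromosome == 44

    def test_t6bs_6hl_totals_315_mb_and_56_percent(self, default_ref):
        summary = ic.summarize_introgression(seg_6h_l_carrier(), default_ref, "6H")
        assert summary.total_present_mb == 315
        assert summary.percent_of_chromosome == 56

    def test_empty_present_set_is_zero(self, default_ref):
        summary = ic.summarize_introgression(
            segs("6H", [(0, 560, "absent")]), default_ref, "6H"
        )
        assert (summary.total_present_mb, summary.percent_of_chromosome) == (0, 0)

    @given(st.lists(st.integers(min_value=1, max_value=40), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_present_and_absent_lengths_sum_to_chromosome(self, lengths):
        total = sum(lengths)
        ref = ic.build_hybrid_reference(
            [], [ic.ChromosomeSpec("x", "barley", total, max(1, total // 2), 1)]
        )
        blocks, pos, state = [], 0, "present"
        for ln in lengths:
            blocks.append((pos, pos + ln, state))
            pos += ln
            state = "absent" if state == "present" else "present"
        summary = ic.summarize_introgression(segs("x", blocks), ref, "x")
        absent = sum(b - a for a, b, s in blocks if s == "absent")
        assert summary.total_present_mb + absent == total


class TestCarrierFrequency:
    @pytest.mark.parametrize("n,k,expected", [(3, 40, 7.5), (6, 50, 12.0), (0, 10, 0.0)])
    def test_percent_to_one_decimal(self, n, k, expected):
        assert ic.carrier_frequency(n, k) == expected

    def test_zero_screened_rejected(self):
        with pytest.raises(ValueError):
            ic.carrier_frequency(1, 0)
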