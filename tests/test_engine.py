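"""Detector semantics, size arithmetic and the classify arbitration rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from splicefx.engine import (
    FORBIDDEN_PAIRS,
    AberrationType,
    SignalKind,
    classify,
    detect_exon_skipping,
    detect_multi_exon_skipping,
    detect_partial_exon_deletion,
    detect_partial_intron_retention,
    detect_pseudoexon,
    detect_whole_intron_retention,
    localize_signals,
)
from splicefx.fixtures import forge_case, mirror_case
from splicefx.model import Thresholds

TH = Thresholds()


def types_of(calls):
    return sorted(c.type.value for c in calls)


class TestLocalize:
    def test_four_signals_always(self, three_exon_plus):
        r = make_record(three_exon_plus, 350)
        signals = localize_signals(r, three_exon_plus, TH)
        assert len(signals) == 4
        assert all(s.inert for s in signals)

    def test_loss_at_native_donor_is_matched(self, three_exon_plus):
        r = make_record(three_exon_plus, 350, {"dl": 200}, {"dl": 0.5})
        dl = [s for s in localize_signals(r, three_exon_plus, TH) if s.kind == SignalKind.DONOR_LOSS][0]
        assert dl.matches_native is not None
        assert dl.matches_native.intron_index == 1

    def test_intronic_gain_locus(self, three_exon_plus):
        r = make_record(three_exon_plus, 350, {"dg": 552}, {"dg": 0.62})
        dg = [s for s in localize_signals(r, three_exon_plus, TH) if s.kind == SignalKind.DONOR_GAIN][0]
        assert dg.locus == ("intron", 2)


class TestPseudoexon:
    def test_inclusive_size_101(self, three_exon_plus):
        # intron 2 spans 465..700; AG at 500, DG at 600 -> 101 bases inclusive
        r = make_record(three_exon_plus, 550, {"ag": 500, "dg": 600}, {"ag": 0.30, "dg": 0.25})
        call = detect_pseudoexon(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH)
        assert call is not None and call.inserted_bp == 101
        assert call.affected == (2, 2)

    def test_oversized_pair_not_called(self):
        case = forge_case("pseudoexonization", {"size": 600}, seed=1)
        assert types_of(classify(case.record, case.transcript)) == ["no_impact"]

    def test_gain_below_threshold(self, three_exon_plus):
        r = make_record(three_exon_plus, 550, {"ag": 500, "dg": 600}, {"ag": 0.04, "dg": 0.25})
        assert detect_pseudoexon(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH) is None

    def test_donor_before_acceptor_not_called(self, three_exon_plus):
        r = make_record(three_exon_plus, 550, {"ag": 600, "dg": 500}, {"ag": 0.3, "dg": 0.3})
        assert detect_pseudoexon(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH) is None


class TestExonSkipping:
    def test_both_flanks_lost_deletes_exon_length(self, three_exon_plus):
        # internal exon (301,464) is 164 bp
        r = make_record(three_exon_plus, 380, {"al": 301, "dl": 464}, {"al": 0.9, "dl": 0.8})
        call = detect_exon_skipping(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH)
        assert call is not None and call.deleted_bp == 164

    def test_losses_on_different_exons_not_single_skip(self, five_exon_plus):
        t = five_exon_plus
        r = make_record(t, 800, {"al": 401, "dl": 820}, {"al": 0.9, "dl": 0.9})
        signals = localize_signals(r, t, TH)
        assert detect_exon_skipping(signals, t, TH) is None
        multi = detect_multi_exon_skipping(signals, t, TH)
        assert multi is not None and multi.affected == (2, 3)

    def test_terminal_losses_flagged_unresolved(self, three_exon_plus):
        # donor of exon 1 lost alone: terminal exon cannot be skipped
        r = make_record(three_exon_plus, 150, {"dl": 200}, {"dl": 0.9})
        calls = classify(r, three_exon_plus, TH)
        assert types_of(calls) == ["no_impact"]
        assert any("unresolved" in n for n in calls[0].notes)


class TestMultiExonSkipping:
    def test_summed_exon_lengths(self, five_exon_plus):
        # exons 2 (90 bp) and 3 (120 bp)
        r = make_record(five_exon_plus, 600, {"al": 401, "dl": 820}, {"al": 0.9, "dl": 0.9})
        call = detect_multi_exon_skipping(localize_signals(r, five_exon_plus, TH), five_exon_plus, TH)
        assert call is not None and call.deleted_bp == 210

    def test_below_threshold_no_call(self, five_exon_plus):
        r = make_record(five_exon_plus, 600, {"al": 401, "dl": 820}, {"al": 0.9, "dl": 0.1})
        assert detect_multi_exon_skipping(localize_signals(r, five_exon_plus, TH), five_exon_plus, TH) is None

    def test_crossed_losses_noted_not_called(self, five_exon_plus):
        # acceptor of exon 4 with donor of exon 2: e2 < e1
        r = make_record(five_exon_plus, 800, {"al": 1001, "dl": 490}, {"al": 0.9, "dl": 0.9})
        calls = classify(r, five_exon_plus, TH)
        assert types_of(calls) == ["no_impact"]
        assert any("crossed-loss-pair" in n for n in calls[0].notes)


class TestWholeIntronRetention:
    def test_intron_length_inserted(self):
        case = forge_case("whole_intron_retention", seed=4)
        calls = classify(case.record, case.transcript)
        assert types_of(calls) == ["whole_intron_retention"]
        assert calls[0].inserted_bp == case.truth.inserted_bp

    def test_lone_donor_loss_falls_through(self, three_exon_plus):
        r = make_record(three_exon_plus, 250, {"dl": 200}, {"dl": 0.5})
        signals = localize_signals(r, three_exon_plus, TH)
        assert detect_whole_intron_retention(signals, three_exon_plus, TH) is None

    def test_partner_site_beyond_window_noted(self):
        case = forge_case("window_limited", seed=6)
        calls = classify(case.record, case.transcript)
        assert types_of(calls) == ["no_impact"]
        assert any("window-limited" in n for n in calls[0].notes)


class TestPartialIntronRetention:
    def test_donor_gain_88_into_intron(self, three_exon_plus):
        # native donor of intron 2 at 464; gain at 552 -> 88 retained bases
        r = make_record(three_exon_plus, 500, {"dg": 552}, {"dg": 0.62})
        calls = detect_partial_intron_retention(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH)
        assert len(calls) == 1 and calls[0].inserted_bp == 88
        assert calls[0].side == "donor"

    def test_acceptor_gain_30_before_acceptor(self, three_exon_plus):
        # native acceptor of intron 1 at 301; gain at 271 -> 30 retained bases
        r = make_record(three_exon_plus, 250, {"ag": 271}, {"ag": 0.07})
        calls = detect_partial_intron_retention(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH)
        assert len(calls) == 1 and calls[0].inserted_bp == 30

    def test_exonic_gain_is_not_retention(self, three_exon_plus):
        r = make_record(three_exon_plus, 350, {"dg": 380}, {"dg": 0.62})
        assert detect_partial_intron_retention(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH) == []

    def test_matching_native_loss_recorded_as_support(self, three_exon_plus):
        r = make_record(three_exon_plus, 500, {"dg": 552, "dl": 464}, {"dg": 0.62, "dl": 0.3})
        calls = detect_partial_intron_retention(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH)
        assert calls[0].has_loss_support()


class TestPartialExonDeletion:
    def test_size_from_native_site_119(self, three_exon_plus):
        """Synthetic analog of the native-vs-predicted anchoring distinction.

        A cryptic donor 119 bases upstream of the annotated donor must yield
        119 deleted bases even when the donor-loss delta position (the
        'predicted' native site) is offset 6 bp from the annotation, which a
        predicted-position computation would misread as 125 bp.
        """
        t = three_exon_plus  # exon 2 donor at 464
        cryptic = 464 - 119
        r = make_record(t, 360, {"dg": cryptic, "dl": 470}, {"dg": 0.8, "dl": 0.3})
        calls = detect_partial_exon_deletion(localize_signals(r, t, TH), t, TH)
        assert len(calls) == 1
        assert calls[0].deleted_bp == 119
        predicted_position_size = abs(470 - cryptic)  # the artifact arithmetic
        assert predicted_position_size == 125
        assert calls[0].deleted_bp != predicted_position_size

    def test_acceptor_gain_inside_exon(self, three_exon_plus):
        r = make_record(three_exon_plus, 330, {"ag": 341}, {"ag": 0.4})
        calls = detect_partial_exon_deletion(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH)
        assert len(calls) == 1 and calls[0].deleted_bp == 40

    def test_gain_at_native_boundary_suppressed(self, three_exon_plus):
        r = make_record(three_exon_plus, 330, {"ag": 301}, {"ag": 0.4})
        assert detect_partial_exon_deletion(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH) == []

    def test_below_gain_threshold(self, three_exon_plus):
        r = make_record(three_exon_plus, 330, {"ag": 341}, {"ag": 0.03})
        assert detect_partial_exon_deletion(localize_signals(r, three_exon_plus, TH), three_exon_plus, TH) == []


class TestClassify:
    def test_silence_is_no_impact(self, three_exon_plus):
        r = make_record(three_exon_plus, 350)
        calls = classify(r, three_exon_plus, TH)
        assert types_of(calls) == ["no_impact"]

    def test_skip_plus_retention_combination(self, five_exon_plus):
        t = five_exon_plus  # skip exon 3 (701..820) + donor gain in intron 1
        r = make_record(
            t, 560, {"al": 701, "dl": 820, "dg": 230},
            {"al": 0.9, "dl": 0.9, "dg": 0.6},
        )
        calls = classify(r, t, TH)
        assert types_of(calls) == ["exon_skipping", "partial_intron_retention"]

    def test_forbidden_pair_resolved_by_score(self, three_exon_plus):
        # exonic AG (deletion, 0.6) vs intronic DG (retention, 0.3): deletion wins
        t = three_exon_plus
        r = make_record(t, 400, {"ag": 341, "dg": 552}, {"ag": 0.6, "dg": 0.3})
        calls = classify(r, t, TH)
        assert types_of(calls) == ["partial_exon_deletion"]
        assert any("conflict" in n for n in calls[0].notes)
        # and the mirror: retention scores higher
        r2 = make_record(t, 400, {"ag": 341, "dg": 552}, {"ag": 0.3, "dg": 0.6})
        assert types_of(classify(r2, t, TH)) == ["partial_intron_retention"]

    def test_gain_pair_consumed_even_when_size_fails(self):
        """An intronic AG/DG pair out of size range must not degrade into
        partial intron retention calls."""
        case = forge_case("pseudoexonization", {"size": 520}, seed=2)
        calls = classify(case.record, case.transcript)
        assert types_of(calls) == ["no_impact"]
        assert any("pseudoexon-size-out-of-range" in n for n in calls[0].notes)


class TestProperties:
    @pytest.mark.parametrize("category", [
        "pseudoexonization", "partial_intron_retention_donor",
        "partial_exon_deletion_acceptor", "exon_skipping",
        "multi_exon_skipping", "whole_intron_retention",
        "combination_skip_retention",
    ])
    def test_strand_mirror_preserves_calls(self, category):
        case = forge_case(category, seed=13)
        mirrored = mirror_case(case)
        original = [(c.type, c.inserted_bp, c.deleted_bp) for c in classify(case.record, case.transcript)]
        flipped = [(c.type, c.inserted_bp, c.deleted_bp) for c in classify(mirrored.record, mirrored.transcript)]
        assert original == flipped

    @settings(derandomize=True, max_examples=300)
    @given(
        scores=st.lists(st.floats(0, 1, width=32), min_size=4, max_size=4),
        dps=st.lists(st.integers(-600, 600), min_size=4, max_size=4),
    )
    def test_fuzzed_signals_never_forbidden_pairs(self, five_exon_plus, scores, dps):
        r = make_record(five_exon_plus, 750)
        r = type(r)(
            variant=r.variant, gene_symbol=r.gene_symbol,
            ds_ag=scores[0], ds_al=scores[1], ds_dg=scores[2], ds_dl=scores[3],
            dp_ag=dps[0], dp_al=dps[1], dp_dg=dps[2], dp_dl=dps[3],
        )
        emitted = {c.type for c in classify(r, five_exon_plus, TH)}
        for pair in FORBIDDEN_PAIRS:
            assert not pair <= emitted

    def test_threshold_monotonicity_on_detectors(self, small_corpus):
        """Any detector firing at a stricter threshold pair also fires at a
        looser one."""
        gains = [0.02, 0.05, 0.1, 0.2]
        losses = [0.05, 0.1, 0.2, 0.4]
        detectors = [
            detect_pseudoexon, detect_exon_skipping, detect_multi_exon_skipping,
            detect_whole_intron_retention,
            detect_partial_intron_retention, detect_partial_exon_deletion,
        ]
        for case in small_corpus[:22]:
            for det in detectors:
                fired = {}
                for g in gains:
                    for l in losses:
                        th = Thresholds(gain_call_threshold=g, loss_call_threshold=l)
                        signals = localize_signals(case.record, case.transcript, th)
                        out = det(signals, case.transcript, th)
                        fired[(g, l)] = bool(out)
                for g1 in gains:
                    for l1 in losses:
                        for g2 in gains:
                            for l2 in losses:
                                if g1 <= g2 and l1 <= l2 and fired[(g2, l2)]:
                                    assert fired[(g1, l1)], (det.__name__, g1, l1, g2, l2)
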