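"""Transcript editing, translation, notation and NMD prediction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicefx.effect import (
    FrameEffect,
    apply_calls,
    format_notation,
    frame_effect,
    nmd_predict,
    predict_protein_effect,
    reference_cds,
    translate_cds,
    _translate,
)
from splicefx.engine import AberrationType, classify
from splicefx.fixtures import forge_case, make_toy_gene

# independent 3-mer oracle for the standard genetic code
_CODON = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _aa in enumerate(_AAS):
    _CODON[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _aa


def oracle_translate(seq):
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa = _CODON.get(codon, "X")
        if aa == "*":
            return "".join(out)
        out.append(aa)
    return "".join(out)


class TestFrameEffect:
    @pytest.mark.parametrize(
        "delta,expected",
        [(0, FrameEffect.IN_FRAME), (-119, FrameEffect.FRAMESHIFT),
         (101, FrameEffect.FRAMESHIFT), (-164, FrameEffect.FRAMESHIFT),
         (210, FrameEffect.IN_FRAME), (-3, FrameEffect.IN_FRAME)],
    )
    def test_examples(self, delta, expected):
        assert frame_effect(delta) == expected

    @settings(derandomize=True, max_examples=200)
    @given(delta=st.integers(-1000, 1000))
    def test_agrees_with_mod3(self, delta):
        assert (frame_effect(delta) == FrameEffect.IN_FRAME) == (delta % 3 == 0)


class TestTranslate:
    def test_stop_consumed_not_printed(self):
        assert translate_cds("ATGGCTTAA") == "MA"

    def test_ambiguous_codon_gives_x(self):
        assert translate_cds("ATGAANGGC") == "MXG"

    def test_trailing_incomplete_codon_ignored(self):
        assert translate_cds("ATGGCTTA") == "MA"  # TA dropped

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("")

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10000))
    def test_matches_independent_oracle(self, seed):
        import random

        rng = random.Random(seed)
        seq = "ATG" + "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 120)))
        assert translate_cds(seq) == oracle_translate(seq)


class TestApplyCalls:
    def test_no_impact_is_identity(self):
        genome, t = make_toy_gene(seed=3)
        from splicefx.engine import AberrationCall

        altered = apply_calls(t, [AberrationCall(type=AberrationType.NO_IMPACT)], genome)
        assert altered.delta_len == 0
        expected = tuple((s, e) for s, e in t.exons)
        assert altered.segments == expected
        assert altered.cds_sequence == reference_cds(t, genome)

    def test_skip_bookkeeping(self):
        case = forge_case("exon_skipping", seed=8)
        calls = classify(case.record, case.transcript)
        altered = apply_calls(case.transcript, calls, case.genome, case.record.variant)
        assert altered.delta_len == -case.truth.deleted_bp
        assert len(altered.segments) == case.transcript.n_exons - 1

    def test_pseudoexon_adds_segment_and_junctions(self):
        case = forge_case("pseudoexonization", {"size": 101}, seed=8)
        t = case.transcript
        calls = classify(case.record, t)
        altered = apply_calls(t, calls, case.genome, case.record.variant)
        assert altered.delta_len == 101
        assert len(altered.segments) == t.n_exons + 1
        assert len(altered.junction_offsets) == t.n_exons  # one extra junction

    def test_length_conservation_across_categories(self, small_corpus):
        for case in small_corpus:
            calls = [c for c in classify(case.record, case.transcript)
                     if c.type != AberrationType.NO_IMPACT]
            if not calls:
                continue
            altered = apply_calls(case.transcript, calls, case.genome, case.record.variant)
            ref_len = sum(e - s + 1 for s, e in case.transcript.exons)
            assert len(altered.mrna_seq) - ref_len == altered.delta_len
            assert altered.delta_len == case.truth.delta_len

    def test_call_for_missing_feature_is_fatal(self):
        genome, t = make_toy_gene(n_exons=3, seed=3)
        from splicefx.effect import ConsistencyError
        from splicefx.engine import AberrationCall

        bad = AberrationCall(
            type=AberrationType.EXON_SKIPPING, deleted_bp=1, feature="exon", affected=(9, 9)
        )
        with pytest.raises(ConsistencyError):
            apply_calls(t, [bad], genome)


class TestNotation:
    def test_no_change_is_dot(self):
        assert format_notation("MABCDEF", "MABCDEF", in_frame=True) == "."

    def test_inframe_deletion_blank_brackets(self):
        wt = "MRSTABCQWERTYKLMNP"
        # delete codons 10-12 (QWE -> gone), no missense
        mut = wt[:9] + wt[12:]
        notation = format_notation(wt, mut, in_frame=True)
        assert notation == f"{wt[6:9]}[]{wt[12:15]}"

    def test_frameshift_novel_then_stop(self):
        wt = "MRSTABCDEFGH"
        mut = wt[:5] + "QWXYZ"  # diverges at codon 6, 5 novel residues, stop
        notation = format_notation(wt, mut, in_frame=False, stop_found=True)
        assert notation == f"{wt[2:5]}[QWXYZ*]"

    def test_missense_within_inframe_event(self):
        wt = "MABCDEFGHIJ"
        mut = "MABCXYFGHIJ"  # codons 5-6 replaced
        notation = format_notation(wt, mut, in_frame=True)
        assert notation == f"{wt[1:4]}[XY]{wt[6:9]}"

    def test_prefix_shorter_near_start(self):
        assert format_notation("MAB", "MXB", in_frame=True).startswith("M[")


class TestNmd:
    def test_ptc_far_upstream_triggers(self):
        assert nmd_predict(100, [150, 300]) is True  # 200 nt upstream of last junction

    def test_ptc_in_last_exon_does_not(self):
        assert nmd_predict(290, [150, 300]) is False  # only 10 nt upstream

    def test_no_junction_no_nmd(self):
        assert nmd_predict(10, []) is False

    def test_boundary_is_exclusive(self):
        assert nmd_predict(250, [300]) is False  # exactly 50 nt
        assert nmd_predict(249, [300]) is True


class TestProteinEffect:
    def test_skip_of_inframe_exon_gives_clean_deletion(self):
        # force an exon whose length is a multiple of 3
        genome, t = make_toy_gene(n_exons=4, exon_lens=[120, 90, 120, 120],
                                  intron_lens=[300, 300, 300], seed=5)
        from conftest import make_record

        acc = t.acceptor_site(1).pos
        don = t.donor_site(2).pos
        r = make_record(t, acc + 45, {"al": acc, "dl": don}, {"al": 0.9, "dl": 0.9})
        calls = classify(r, t)
        altered = apply_calls(t, calls, genome, None)
        effect = predict_protein_effect(t, altered, genome)
        assert effect.frame == FrameEffect.IN_FRAME
        assert "[" in effect.notation

    def test_frameshift_detected_and_translated(self, small_corpus):
        checked = 0
        for case in small_corpus:
            if case.truth.frame != "frameshift":
                continue
            calls = [c for c in classify(case.record, case.transcript)
                     if c.type != AberrationType.NO_IMPACT]
            altered = apply_calls(case.transcript, calls, case.genome, case.record.variant)
            effect = predict_protein_effect(case.transcript, altered, case.genome)
            assert effect.frame == FrameEffect.FRAMESHIFT
            checked += 1
        assert checked > 0

    def test_notation_roundtrip_on_corpus(self, small_corpus):
        """The notation, read as an edit script, must rebuild the mutant protein."""
        for case in small_corpus:
            calls = [c for c in classify(case.record, case.transcript)
                     if c.type != AberrationType.NO_IMPACT]
            if not calls or not case.transcript.is_coding():
                continue
            altered = apply_calls(case.transcript, calls, case.genome, case.record.variant)
            effect = predict_protein_effect(case.transcript, altered, case.genome)
            wt, _ = _translate(reference_cds(case.transcript, case.genome))
            mut, _ = _translate(altered.mrna_seq[altered.cds_start_offset:])
            assert rebuild_from_notation(wt, mut, effect.notation) == mut, case.name


def rebuild_from_notation(wt: str, mut: str, notation: str) -> str:
    """Apply the bracket notation to the wild type as an edit script."""
    if notation == ".":
        return wt
    pre, rest = notation.split("[")
    inner, post = rest.split("]")
    i = 0
    while i < min(len(wt), len(mut)) and wt[i] == mut[i]:
        i += 1
    assert wt[max(0, i - 3) : i] == pre
    if inner.endswith("*") or post == "":
        return wt[:i] + inner.rstrip("*")
    k = len(mut) - i - len(inner)
    assert wt[len(wt) - k : len(wt) - k + 3] == post
    return wt[:i] + inner + wt[len(wt) - k :]
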