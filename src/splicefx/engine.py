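"""Aberration-calling engine.

Places the four SpliceAI gain/loss signals on the transcript, applies the
calling thresholds, and emits typed aberration calls with exact inserted and
deleted sizes.  All size arithmetic is anchored on the transcript's *native*
splice sites (annotated exon boundaries), never on SpliceAI-predicted site
positions — this is what makes partial-retention/deletion sizes exact.

Size conventions (transcript orientation, 1-based inclusive coordinates):

* pseudoexon: acceptor gain at the first base, donor gain at the last base of
  the novel exon, so inserted_bp = donor - acceptor + 1;
* partial intron retention: inserted_bp = distance between the native anchor
  (donor for a donor gain, acceptor for an acceptor gain) and the cryptic
  site, i.e. the count of retained intronic bases;
* partial exon deletion: deleted_bp = distance between the native boundary
  and the cryptic exonic site, i.e. the count of lost exonic bases;
* exon skipping / whole intron retention: the genomic length of the skipped
  exon(s) / retained intron.

Three aberration combinations can never be emitted together for one variant:
exon skipping with multi-exon skipping, exon skipping with whole intron
retention, and partial exon deletion with partial intron retention.  When
detector outputs collide on a forbidden pair, the call whose driving signal
scores higher wins; on a tie, the loss-driven call wins, and for the
(gain-driven) partial deletion / partial retention pair the call with
supporting native-loss evidence wins, falling back to partial intron
retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from .model import (
    ANALYSIS_WINDOW,
    SiteKind,
    SpliceAIRecord,
    SpliceSite,
    Thresholds,
    TranscriptModel,
    resolve_dp,
)


class SignalKind(str, Enum):
    ACCEPTOR_GAIN = "acceptor_gain"
    ACCEPTOR_LOSS = "acceptor_loss"
    DONOR_GAIN = "donor_gain"
    DONOR_LOSS = "donor_loss"

    @property
    def is_gain(self) -> bool:
        return self in (SignalKind.ACCEPTOR_GAIN, SignalKind.DONOR_GAIN)

    @property
    def site_kind(self) -> SiteKind:
        if self in (SignalKind.ACCEPTOR_GAIN, SignalKind.ACCEPTOR_LOSS):
            return SiteKind.ACCEPTOR
        return SiteKind.DONOR


@dataclass(frozen=True)
class SpliceSignal:
    """One of the four delta-score signals, localized on the transcript."""

    kind: SignalKind
    score: float
    genomic_pos: int
    locus: tuple[str, Optional[int]]  # ("exon"|"intron"|"outside", tx index)
    matches_native: Optional[SpliceSite] = None
    inert: bool = False  # score below the noise floor


class AberrationType(str, Enum):
    PSEUDOEXONIZATION = "pseudoexonization"
    PARTIAL_INTRON_RETENTION = "partial_intron_retention"
    PARTIAL_EXON_DELETION = "partial_exon_deletion"
    EXON_SKIPPING = "exon_skipping"
    MULTI_EXON_SKIPPING = "multi_exon_skipping"
    WHOLE_INTRON_RETENTION = "whole_intron_retention"
    NO_IMPACT = "no_impact"


#: pairs that can never be reported together for one variant
FORBIDDEN_PAIRS = frozenset(
    {
        frozenset({AberrationType.EXON_SKIPPING, AberrationType.MULTI_EXON_SKIPPING}),
        frozenset({AberrationType.EXON_SKIPPING, AberrationType.WHOLE_INTRON_RETENTION}),
        frozenset(
            {AberrationType.PARTIAL_EXON_DELETION, AberrationType.PARTIAL_INTRON_RETENTION}
        ),
    }
)

_LOSS_DRIVEN = frozenset(
    {
        AberrationType.EXON_SKIPPING,
        AberrationType.MULTI_EXON_SKIPPING,
        AberrationType.WHOLE_INTRON_RETENTION,
    }
)


@dataclass(frozen=True)
class AberrationCall:
    """One predicted splicing aberration.

    ``affected`` is the transcript-orientation index range of the affected
    feature(s) (exon or intron per ``feature``).  For cryptic-site calls,
    ``cryptic_pos`` is the genomic position of the novel splice site and
    ``side`` says which native boundary anchors the size.  ``tx_interval``
    holds the (first, last) genomic bases of an inserted pseudoexon in
    transcript orientation.
    """

    type: AberrationType
    inserted_bp: int = 0
    deleted_bp: int = 0
    feature: Optional[str] = None  # "exon" | "intron"
    affected: Optional[tuple[int, int]] = None
    side: Optional[str] = None  # "donor" | "acceptor"
    cryptic_pos: Optional[int] = None
    tx_interval: Optional[tuple[int, int]] = None
    window_limited: bool = False
    evidence: tuple[SpliceSignal, ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.inserted_bp < 0 or self.deleted_bp < 0:
            raise ValueError("sizes must be >= 0")

    @property
    def driving_score(self) -> float:
        return max((s.score for s in self.evidence), default=0.0)

    def has_loss_support(self) -> bool:
        return any(not s.kind.is_gain and s.matches_native for s in self.evidence)


def localize_signals(
    r: SpliceAIRecord, t: TranscriptModel, th: Thresholds
) -> list[SpliceSignal]:
    """Place all four delta-score signals on the transcript.

    Returns exactly four signals in the fixed order AG, AL, DG, DL.  A loss
    signal whose score clears the noise floor and whose resolved position
    coincides with a native site of the matching kind carries that site in
    ``matches_native``.
    """
    raw = [
        (SignalKind.ACCEPTOR_GAIN, r.ds_ag, r.dp_ag),
        (SignalKind.ACCEPTOR_LOSS, r.ds_al, r.dp_al),
        (SignalKind.DONOR_GAIN, r.ds_dg, r.dp_dg),
        (SignalKind.DONOR_LOSS, r.ds_dl, r.dp_dl),
    ]
    native = {
        (s.kind, s.pos): s
        for s in (
            [t.donor_site(i) for i in range(1, t.n_introns + 1)]
            + [t.acceptor_site(i) for i in range(1, t.n_introns + 1)]
        )
    }
    out = []
    for kind, score, dp in raw:
        pos = resolve_dp(r.variant, dp, t.strand, th.dp_convention)
        inert = score < th.noise_floor
        matched = None
        if not kind.is_gain and not inert:
            matched = native.get((kind.site_kind, pos))
        out.append(
            SpliceSignal(
                kind=kind,
                score=score,
                genomic_pos=pos,
                locus=t.locate(pos),
                matches_native=matched,
                inert=inert,
            )
        )
    return out


def _signal(signals: Sequence[SpliceSignal], kind: SignalKind) -> SpliceSignal:
    for s in signals:
        if s.kind == kind:
            return s
    raise ValueError(f"no {kind} signal present")


def _within_window(variant_pos: int, pos: int) -> bool:
    return abs(pos - variant_pos) <= ANALYSIS_WINDOW


def detect_pseudoexon(
    signals: Sequence[SpliceSignal], t: TranscriptModel, th: Thresholds
) -> Optional[AberrationCall]:
    """Novel exon from a paired cryptic acceptor + donor inside one intron.

    Fires when both gains clear the gain threshold, lie in the same intron
    with the acceptor 5' of the donor (transcript orientation), and the
    inclusive size falls within the allowed pseudoexon range.
    """
    ag = _signal(signals, SignalKind.ACCEPTOR_GAIN)
    dg = _signal(signals, SignalKind.DONOR_GAIN)
    cand = _pseudoexon_candidate(ag, dg, t, th)
    if cand is None:
        return None
    size, intron = cand
    if not th.pseudoexon_min_bp <= size <= th.pseudoexon_max_bp:
        return None
    first, last = ag.genomic_pos, dg.genomic_pos
    return AberrationCall(
        type=AberrationType.PSEUDOEXONIZATION,
        inserted_bp=size,
        feature="intron",
        affected=(intron, intron),
        tx_interval=(first, last),
        evidence=(ag, dg),
    )


def _pseudoexon_candidate(
    ag: SpliceSignal, dg: SpliceSignal, t: TranscriptModel, th: Thresholds
) -> Optional[tuple[int, int]]:
    """(size, intron index) for an intronic AG/DG pair above threshold, any size."""
    if ag.score < th.gain_call_threshold or dg.score < th.gain_call_threshold:
        return None
    if ag.locus[0] != "intron" or dg.locus[0] != "intron":
        return None
    if ag.locus[1] != dg.locus[1]:
        return None
    span = t.tx_distance(ag.genomic_pos, dg.genomic_pos)
    if span < 0:
        return None
    return (span + 1, ag.locus[1])


def detect_exon_skipping(
    signals: Sequence[SpliceSignal], t: TranscriptModel, th: Thresholds
) -> Optional[AberrationCall]:
    """Whole-exon loss: both native sites of one internal exon are lost."""
    al = _signal(signals, SignalKind.ACCEPTOR_LOSS)
    dl = _signal(signals, SignalKind.DONOR_LOSS)
    if al.score < th.loss_call_threshold or dl.score < th.loss_call_threshold:
        return None
    if al.matches_native is None or dl.matches_native is None:
        return None
    # acceptor of intron i is the first base of exon i+1; donor of intron j
    # is the last base of exon j — same exon means j == i+1
    exon_a = al.matches_native.intron_index + 1
    exon_d = dl.matches_native.intron_index
    if exon_a != exon_d:
        return None
    return AberrationCall(
        type=AberrationType.EXON_SKIPPING,
        deleted_bp=t.exon_length(exon_a),
        feature="exon",
        affected=(exon_a, exon_a),
        evidence=(al, dl),
    )


def detect_multi_exon_skipping(
    signals: Sequence[SpliceSignal],
    t: TranscriptModel,
    th: Thresholds,
    variant_pos: Optional[int] = None,
) -> Optional[AberrationCall]:
    """Loss of the acceptor of exon e1 and the donor of exon e2 > e1."""
    al = _signal(signals, SignalKind.ACCEPTOR_LOSS)
    dl = _signal(signals, SignalKind.DONOR_LOSS)
    if al.score < th.loss_call_threshold or dl.score < th.loss_call_threshold:
        return None
    if al.matches_native is None or dl.matches_native is None:
        return None
    e1 = al.matches_native.intron_index + 1
    e2 = dl.matches_native.intron_index
    if e2 <= e1:
        return None
    deleted = sum(t.exon_length(e) for e in range(e1, e2 + 1))
    limited = variant_pos is not None and not (
        _within_window(variant_pos, t.acceptor_site(e1 - 1).pos)
        and _within_window(variant_pos, t.donor_site(e2).pos)
    )
    return AberrationCall(
        type=AberrationType.MULTI_EXON_SKIPPING,
        deleted_bp=deleted,
        feature="exon",
        affected=(e1, e2),
        window_limited=limited,
        evidence=(al, dl),
    )


def detect_whole_intron_retention(
    signals: Sequence[SpliceSignal],
    t: TranscriptModel,
    th: Thresholds,
    variant_pos: Optional[int] = None,
) -> Optional[AberrationCall]:
    """Both native sites flanking one intron are lost -> intron retained."""
    al = _signal(signals, SignalKind.ACCEPTOR_LOSS)
    dl = _signal(signals, SignalKind.DONOR_LOSS)
    if al.score < th.loss_call_threshold or dl.score < th.loss_call_threshold:
        return None
    if al.matches_native is None or dl.matches_native is None:
        return None
    if al.matches_native.intron_index != dl.matches_native.intron_index:
        return None
    intron = dl.matches_native.intron_index
    lo, hi = t.intron_interval(intron)
    limited = variant_pos is not None and not (
        _within_window(variant_pos, lo) and _within_window(variant_pos, hi)
    )
    return AberrationCall(
        type=AberrationType.WHOLE_INTRON_RETENTION,
        inserted_bp=t.intron_length(intron),
        feature="intron",
        affected=(intron, intron),
        window_limited=limited,
        evidence=(al, dl),
    )


def detect_partial_intron_retention(
    signals: Sequence[SpliceSignal], t: TranscriptModel, th: Thresholds
) -> list[AberrationCall]:
    """Cryptic intronic site extends the adjacent exon into the intron.

    A donor gain in intron i moves the effective donor ``inserted_bp`` bases
    downstream of the native donor; an acceptor gain moves the effective
    acceptor upstream of the native acceptor.  Sizes are measured against the
    native site.  A matching native-site loss strengthens the call but is not
    required — a cryptic site can be used alongside the native one.
    """
    calls = []
    al = _signal(signals, SignalKind.ACCEPTOR_LOSS)
    dl = _signal(signals, SignalKind.DONOR_LOSS)
    for gain, loss in (
        (_signal(signals, SignalKind.DONOR_GAIN), dl),
        (_signal(signals, SignalKind.ACCEPTOR_GAIN), al),
    ):
        if gain.score < th.gain_call_threshold or gain.locus[0] != "intron":
            continue
        intron = gain.locus[1]
        if gain.kind == SignalKind.DONOR_GAIN:
            size = t.tx_distance(t.donor_site(intron).pos, gain.genomic_pos)
            side = "donor"
        else:
            size = t.tx_distance(gain.genomic_pos, t.acceptor_site(intron).pos)
            side = "acceptor"
        if size <= 0:  # degenerate: gain at or beyond the native anchor
            continue
        supporting = (
            (loss,)
            if loss.matches_native is not None
            and loss.matches_native.intron_index == intron
            and loss.matches_native.kind == gain.kind.site_kind
            else ()
        )
        calls.append(
            AberrationCall(
                type=AberrationType.PARTIAL_INTRON_RETENTION,
                inserted_bp=size,
                feature="intron",
                affected=(intron, intron),
                side=side,
                cryptic_pos=gain.genomic_pos,
                evidence=(gain,) + supporting,
            )
        )
    return calls


def detect_partial_exon_deletion(
    signals: Sequence[SpliceSignal], t: TranscriptModel, th: Thresholds
) -> list[AberrationCall]:
    """Cryptic exonic site deletes part of the exon.

    An acceptor gain inside exon e moves the effective acceptor downstream of
    the native one (deleting the exon's 5' part); a donor gain moves the
    effective donor upstream (deleting the 3' part).  Sizes are always
    computed against the transcript's annotated native site, never against a
    SpliceAI-predicted native position.
    """
    calls = []
    for gain in (
        _signal(signals, SignalKind.ACCEPTOR_GAIN),
        _signal(signals, SignalKind.DONOR_GAIN),
    ):
        if gain.score < th.gain_call_threshold or gain.locus[0] != "exon":
            continue
        exon = gain.locus[1]
        if gain.kind == SignalKind.ACCEPTOR_GAIN:
            if exon == 1:  # the first exon has no native acceptor
                continue
            native = t.acceptor_site(exon - 1).pos
            size = t.tx_distance(native, gain.genomic_pos)
            side = "acceptor"
        else:
            if exon == t.n_exons:  # the last exon has no native donor
                continue
            native = t.donor_site(exon).pos
            size = t.tx_distance(gain.genomic_pos, native)
            side = "donor"
        if size <= 0:  # gain exactly at (or outside) the native boundary
            continue
        calls.append(
            AberrationCall(
                type=AberrationType.PARTIAL_EXON_DELETION,
                deleted_bp=size,
                feature="exon",
                affected=(exon, exon),
                side=side,
                cryptic_pos=gain.genomic_pos,
                evidence=(gain,),
            )
        )
    return calls


def _resolve_forbidden(calls: list[AberrationCall]) -> tuple[list[AberrationCall], list[str]]:
    """Drop the weaker member of every forbidden pair; return kept calls + notes."""
    notes: list[str] = []
    kept = list(calls)
    changed = True
    while changed:
        changed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                if frozenset({a.type, b.type}) not in FORBIDDEN_PAIRS:
                    continue
                winner, loser = _arbitrate(a, b)
                notes.append(
                    f"conflict:{loser.type.value}(score={loser.driving_score:.2f})"
                    f"<{winner.type.value}(score={winner.driving_score:.2f})"
                )
                kept.remove(loser)
                changed = True
                break
            if changed:
                break
    return kept, notes


def _arbitrate(a: AberrationCall, b: AberrationCall) -> tuple[AberrationCall, AberrationCall]:
    if a.driving_score > b.driving_score:
        return a, b
    if b.driving_score > a.driving_score:
        return b, a
    # tie: the loss-driven call wins
    a_loss, b_loss = a.type in _LOSS_DRIVEN, b.type in _LOSS_DRIVEN
    if a_loss and not b_loss:
        return a, b
    if b_loss and not a_loss:
        return b, a
    # both gain-driven (partial deletion vs partial retention): prefer the
    # call with supporting native-loss evidence, else partial intron retention
    if a.has_loss_support() and not b.has_loss_support():
        return a, b
    if b.has_loss_support() and not a.has_loss_support():
        return b, a
    if a.type == AberrationType.PARTIAL_INTRON_RETENTION:
        return a, b
    if b.type == AberrationType.PARTIAL_INTRON_RETENTION:
        return b, a
    return a, b


_TYPE_ORDER = {
    AberrationType.PSEUDOEXONIZATION: 0,
    AberrationType.PARTIAL_INTRON_RETENTION: 1,
    AberrationType.PARTIAL_EXON_DELETION: 2,
    AberrationType.EXON_SKIPPING: 3,
    AberrationType.MULTI_EXON_SKIPPING: 4,
    AberrationType.WHOLE_INTRON_RETENTION: 5,
    AberrationType.NO_IMPACT: 6,
}


def classify(
    r: SpliceAIRecord, t: TranscriptModel, th: Optional[Thresholds] = None
) -> list[AberrationCall]:
    """Run all detectors and arbitrate into a final list of calls.

    Always returns at least one call; when nothing fires, a single
    ``no_impact`` call carrying any unresolved-evidence notes.
    """
    th = th or Thresholds()
    signals = localize_signals(r, t, th)
    ag = _signal(signals, SignalKind.ACCEPTOR_GAIN)
    al = _signal(signals, SignalKind.ACCEPTOR_LOSS)
    dg = _signal(signals, SignalKind.DONOR_GAIN)
    dl = _signal(signals, SignalKind.DONOR_LOSS)
    vpos = r.variant.pos
    notes: list[str] = []
    calls: list[AberrationCall] = []

    # --- gain pathway ----------------------------------------------------
    # An intronic AG/DG pair is a pseudoexon candidate; once paired, the two
    # gains are interpreted only as a (possible) pseudoexon, never re-read as
    # two partial intron retentions.
    consumed_gains: set[SignalKind] = set()
    cand = _pseudoexon_candidate(ag, dg, t, th)
    if cand is not None:
        size, intron = cand
        consumed_gains = {SignalKind.ACCEPTOR_GAIN, SignalKind.DONOR_GAIN}
        pe = detect_pseudoexon(signals, t, th)
        if pe is not None:
            calls.append(pe)
        else:
            notes.append(
                f"pseudoexon-size-out-of-range:{size}bp"
                f"(allowed {th.pseudoexon_min_bp}-{th.pseudoexon_max_bp})"
            )
    if not consumed_gains:
        calls.extend(detect_partial_intron_retention(signals, t, th))
        calls.extend(detect_partial_exon_deletion(signals, t, th))
    for g in (ag, dg):
        if (
            g.score >= th.gain_call_threshold
            and g.locus[0] == "outside"
            and g.kind not in consumed_gains
        ):
            notes.append(f"{g.kind.value}-outside-transcript@{g.genomic_pos}")

    # --- loss pathway ----------------------------------------------------
    loss_call = (
        detect_exon_skipping(signals, t, th)
        or detect_multi_exon_skipping(signals, t, th, variant_pos=vpos)
        or detect_whole_intron_retention(signals, t, th, variant_pos=vpos)
    )
    if loss_call is not None:
        calls.append(loss_call)
    else:
        notes.extend(_loss_notes(al, dl, t, th, vpos))

    calls, conflict_notes = _resolve_forbidden(calls)
    notes.extend(conflict_notes)

    calls.sort(key=lambda c: (_TYPE_ORDER[c.type], c.affected or (0, 0)))
    if not calls:
        return [AberrationCall(type=AberrationType.NO_IMPACT, notes=tuple(notes))]
    if notes:
        first = calls[0]
        calls[0] = replace(first, notes=first.notes + tuple(notes))
    return calls


def _loss_notes(
    al: SpliceSignal,
    dl: SpliceSignal,
    t: TranscriptModel,
    th: Thresholds,
    vpos: int,
) -> list[str]:
    """Explain why above-threshold losses did not combine into a call."""
    notes = []
    strong_al = al.score >= th.loss_call_threshold
    strong_dl = dl.score >= th.loss_call_threshold
    if strong_al and strong_dl and al.matches_native and dl.matches_native:
        e1 = al.matches_native.intron_index + 1
        e2 = dl.matches_native.intron_index
        if e2 < e1 - 1:
            notes.append(f"crossed-loss-pair:acceptor-exon{e1},donor-exon{e2}")
    for sig, name in ((al, "acceptor_loss"), (dl, "donor_loss")):
        if sig.score >= th.loss_call_threshold and sig.matches_native is None:
            notes.append(f"{name}-at-non-native-position@{sig.genomic_pos}")
    # a lone matched native loss: report, and flag when the partner site of
    # its intron lies beyond the analysis window (whole intron retention /
    # multi-exon skipping can then not be assessed)
    lone = None
    if strong_al and al.matches_native and not (strong_dl and dl.matches_native):
        lone = al
    elif strong_dl and dl.matches_native and not (strong_al and al.matches_native):
        lone = dl
    if lone is not None:
        intron = lone.matches_native.intron_index
        partner = (
            t.acceptor_site(intron)
            if lone.matches_native.kind == SiteKind.DONOR
            else t.donor_site(intron)
        )
        if not _within_window(vpos, partner.pos):
            notes.append(
                f"window-limited:partner-{partner.kind.value}-of-intron{intron}"
                "-beyond-analysis-window"
            )
        else:
            notes.append(f"single-native-{lone.kind.value}-unresolved")
    # terminal-exon geometry note: a matched loss pair on terminal exon
    # boundaries that forms no skip (first/last exon cannot be skipped) is
    # covered by the crossed-pair / lone-loss notes above.
    return notes
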