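"""Transcript reconstruction and protein-level consequence prediction.

Aberration calls are applied to the reference exon structure to build the
altered mRNA, the coding sequence is re-extracted and translated, and the
consequence is summarized as a reading-frame effect, a bracketed amino-acid
notation, and an NMD/truncation flag.

Notation format: up to three wild-type residues preceding the first changed
residue, then the novel residues inside square brackets.  For frameshifts
the bracket runs through the novel stop, printed as ``*`` inside the
brackets.  For in-frame events the bracket closes where the mutant sequence
re-synchronizes with the wild type (longest-common-suffix alignment) and is
followed by three wild-type residues; an in-frame deletion with no missense
change therefore prints as ``XXX[]YYY``.  Deleted amino acids are never
shown.  No protein change prints as ``.``.

NMD is predicted by the canonical 50-nt rule: a premature termination codon
more than ``nmd_distance`` nucleotides upstream of the last exon–exon
junction of the *altered* transcript triggers decay; otherwise a truncated
(or elongated, for frameshifts running past the native stop) protein is
predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from Bio.Seq import Seq

from .engine import AberrationCall, AberrationType
from .model import GenomeRef, TranscriptModel, Variant, reverse_complement


class ConsistencyError(ValueError):
    """An aberration call references transcript features that do not exist."""


class FrameEffect(str, Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT = "frameshift"
    NONE = "none"


def frame_effect(delta_len: int) -> FrameEffect:
    """Reading-frame effect of a net coding-length change."""
    return FrameEffect.IN_FRAME if delta_len % 3 == 0 else FrameEffect.FRAMESHIFT


def translate_cds(cds_sequence: str) -> str:
    """Standard-code translation up to (not including) the first stop codon.

    A trailing incomplete codon is ignored; any codon containing N yields X.
    """
    if not cds_sequence:
        raise ValueError("empty coding sequence")
    aa, _ = _translate(cds_sequence)
    return aa


def _translate(seq: str) -> tuple[str, bool]:
    """(residues before first stop, whether a stop codon was reached)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    if not trimmed:
        return ("", False)
    full = str(Seq(trimmed).translate())
    stop = full.find("*")
    if stop == -1:
        return (full, False)
    return (full[:stop], True)


@dataclass
class _Segment:
    first: int  # tx-orientation first genomic base
    last: int  # tx-orientation last genomic base
    origins: set  # transcript exon indices this segment derives from (empty: inserted)


@dataclass(frozen=True)
class AlteredTranscript:
    """The spliced product implied by a set of aberration calls.

    ``segments`` are (first, last) genomic base pairs in transcript
    orientation; ``junction_offsets`` give, for each segment junction, the
    number of mRNA nucleotides 5' of it; ``delta_len`` is the net bp change
    relative to the reference mRNA.
    """

    segments: tuple[tuple[int, int], ...]
    mrna_seq: str
    mrna_positions: tuple[int, ...]
    junction_offsets: tuple[int, ...]
    delta_len: int
    cds_sequence: str
    cds_start_offset: Optional[int]  # 0-based index of start codon in mrna_seq
    start_disrupted: bool = False
    stop_region_lost: bool = False


def _segment_seq(
    genome: GenomeRef, contig: str, seg: _Segment, strand: str, variant: Optional[Variant]
) -> str:
    lo, hi = min(seg.first, seg.last), max(seg.first, seg.last)
    s = genome.fetch(contig, lo, hi)
    if variant is not None and variant.contig == contig and lo <= variant.pos <= hi:
        i = variant.pos - lo
        s = s[:i] + variant.alt.upper() + s[i + 1 :]
    return s if strand == "+" else reverse_complement(s)


def _find_segment(segments: list[_Segment], exon_index: int) -> _Segment:
    for seg in segments:
        if exon_index in seg.origins:
            return seg
    raise ConsistencyError(f"exon {exon_index} absent from the altered structure")


def apply_calls(
    t: TranscriptModel,
    calls: Sequence[AberrationCall],
    genome: GenomeRef,
    variant: Optional[Variant] = None,
) -> AlteredTranscript:
    """Edit the exon structure per the calls and rebuild the mRNA.

    Pseudoexons insert a segment, (multi-)exon skipping removes exons, whole
    and partial intron retention extend segments into the intron, and partial
    exon deletion trims a segment at the cryptic site.  The variant's
    alternate base is substituted into any retained sequence.
    """
    segments: list[_Segment] = []
    for i in range(1, t.n_exons + 1):
        s, e = t.tx_exon(i)
        first, last = (s, e) if t.strand == "+" else (e, s)
        segments.append(_Segment(first, last, {i}))

    for call in calls:
        if call.type == AberrationType.NO_IMPACT:
            continue
        if call.type in (AberrationType.EXON_SKIPPING, AberrationType.MULTI_EXON_SKIPPING):
            e1, e2 = call.affected
            victims = [_find_segment(segments, e) for e in range(e1, e2 + 1)]
            for v in victims:
                if v in segments:
                    segments.remove(v)
        elif call.type == AberrationType.WHOLE_INTRON_RETENTION:
            (i, _) = call.affected
            up = _find_segment(segments, i)
            down = _find_segment(segments, i + 1)
            if up is down:
                raise ConsistencyError(f"intron {i} already merged")
            up.last = down.last
            up.origins |= down.origins
            segments.remove(down)
        elif call.type == AberrationType.PSEUDOEXONIZATION:
            (i, _) = call.affected
            up = _find_segment(segments, i)
            _find_segment(segments, i + 1)  # consistency: both flanks present
            first, last = call.tx_interval
            segments.insert(segments.index(up) + 1, _Segment(first, last, set()))
        elif call.type == AberrationType.PARTIAL_INTRON_RETENTION:
            (i, _) = call.affected
            if call.side == "donor":
                seg = _find_segment(segments, i)
                seg.last = call.cryptic_pos
            else:
                seg = _find_segment(segments, i + 1)
                seg.first = call.cryptic_pos
        elif call.type == AberrationType.PARTIAL_EXON_DELETION:
            (e, _) = call.affected
            seg = _find_segment(segments, e)
            if call.side == "acceptor":
                seg.first = call.cryptic_pos
            else:
                seg.last = call.cryptic_pos
        else:  # pragma: no cover - exhaustive over the taxonomy
            raise ConsistencyError(f"unknown call type {call.type}")

    step = 1 if t.strand == "+" else -1
    positions: list[int] = []
    chunks: list[str] = []
    junctions: list[int] = []
    for seg in segments:
        positions.extend(range(seg.first, seg.last + step, step))
        chunks.append(_segment_seq(genome, t.contig, seg, t.strand, variant))
        junctions.append(len(positions))
    junctions = junctions[:-1]  # offsets after each junction-preceding segment
    mrna = "".join(chunks)

    ref_len = sum(e - s + 1 for s, e in t.exons)
    delta = sum(c.inserted_bp for c in calls) - sum(c.deleted_bp for c in calls)
    if len(mrna) - ref_len != delta:
        raise ConsistencyError(
            f"bookkeeping mismatch: mRNA changed by {len(mrna) - ref_len} bp, "
            f"calls sum to {delta} bp"
        )

    cds_seq = ""
    start_offset: Optional[int] = None
    start_disrupted = False
    stop_lost = False
    if t.is_coding():
        index = {p: i for i, p in enumerate(positions)}
        start_offset = index.get(t.cds_translation_start())
        if start_offset is None:
            start_disrupted = True
        else:
            end_offset = index.get(t.cds_translation_end())
            if end_offset is None or end_offset < start_offset:
                stop_lost = True
                cds_seq = mrna[start_offset:]
            else:
                cds_seq = mrna[start_offset : end_offset + 1]

    return AlteredTranscript(
        segments=tuple((s.first, s.last) for s in segments),
        mrna_seq=mrna,
        mrna_positions=tuple(positions),
        junction_offsets=tuple(junctions),
        delta_len=delta,
        cds_sequence=cds_seq,
        cds_start_offset=start_offset,
        start_disrupted=start_disrupted,
        stop_region_lost=stop_lost,
    )


def reference_cds(t: TranscriptModel, genome: GenomeRef) -> str:
    """The annotated coding sequence, start through stop codon, tx orientation."""
    if not t.is_coding():
        raise ValueError("non-coding transcript")
    parts = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo <= hi:
            parts.append(genome.fetch(t.contig, lo, hi))
    cds = "".join(parts)
    return cds if t.strand == "+" else reverse_complement(cds)


def nmd_predict(
    ptc_pos: int, junction_offsets: Sequence[int], distance_nt: int = 50
) -> bool:
    """50-nt rule: NMD iff the PTC lies more than ``distance_nt`` nucleotides
    upstream of the last exon–exon junction of the altered transcript.

    ``ptc_pos`` is the 1-based position of the first base of the stop codon in
    the mRNA; each junction offset is the number of nucleotides 5' of that
    junction.  A transcript with no junction (single segment) never triggers
    NMD.
    """
    if not junction_offsets:
        return False
    return (max(junction_offsets) - ptc_pos) > distance_nt


def format_notation(
    wt_protein: str,
    mut_protein: str,
    in_frame: bool,
    stop_found: bool = True,
    first_affected_codon: Optional[int] = None,
) -> str:
    """Bracketed amino-acid notation for the protein-level change."""
    if wt_protein == mut_protein:
        return "."
    if first_affected_codon is None:
        i = 0
        limit = min(len(wt_protein), len(mut_protein))
        while i < limit and wt_protein[i] == mut_protein[i]:
            i += 1
    else:
        i = first_affected_codon
    prefix = wt_protein[max(0, i - 3) : i]
    k = 0
    if in_frame:
        max_k = min(len(wt_protein), len(mut_protein)) - i
        while k < max_k and wt_protein[len(wt_protein) - 1 - k] == mut_protein[
            len(mut_protein) - 1 - k
        ]:
            k += 1
    if in_frame and k > 0:
        novel = mut_protein[i : len(mut_protein) - k]
        following = wt_protein[len(wt_protein) - k : len(wt_protein) - k + 3]
        return f"{prefix}[{novel}]{following}"
    # frameshift, or an in-frame change that terminates without re-syncing
    novel = mut_protein[i:]
    star = "*" if stop_found else ""
    return f"{prefix}[{novel}{star}]"


@dataclass(frozen=True)
class ProteinEffect:
    """Protein-level summary of an altered transcript."""

    frame: FrameEffect
    notation: str
    ptc_mrna_pos: Optional[int]  # 1-based first base of a premature stop codon
    nmd_predicted: bool
    truncated: bool
    notes: tuple[str, ...] = ()


def predict_protein_effect(
    t: TranscriptModel,
    altered: AlteredTranscript,
    genome: GenomeRef,
    nmd_distance_nt: int = 50,
) -> ProteinEffect:
    """Translate the altered transcript and summarize the consequence."""
    if not t.is_coding():
        return ProteinEffect(
            FrameEffect.NONE, ".", None, False, False, ("non-coding-transcript",)
        )
    frame = frame_effect(altered.delta_len) if altered.delta_len != 0 else (
        FrameEffect.NONE if altered.segments == tuple(
            (s, e) if t.strand == "+" else (e, s) for s, e in t.exons
        ) else FrameEffect.IN_FRAME
    )
    if altered.start_disrupted:
        return ProteinEffect(
            frame, ".", None, False, False, ("start-codon-disrupted",)
        )
    wt_protein, _ = _translate(reference_cds(t, genome))
    coding_and_beyond = altered.mrna_seq[altered.cds_start_offset :]
    mut_protein, stop_found = _translate(coding_and_beyond)
    notes: list[str] = []
    if altered.stop_region_lost:
        notes.append("native-stop-region-lost")
    if not stop_found:
        notes.append("no-stop-codon-found")

    ptc_pos: Optional[int] = None
    if stop_found:
        stop_offset = altered.cds_start_offset + 3 * len(mut_protein)  # 0-based
        ref_stop_first = (
            t.cds_end - 2 if t.strand == "+" else t.cds_start + 2
        )
        native_stop_here = (
            stop_offset < len(altered.mrna_positions)
            and altered.mrna_positions[stop_offset] == ref_stop_first
        )
        if not native_stop_here:
            ptc_pos = stop_offset + 1

    nmd = (
        nmd_predict(ptc_pos, altered.junction_offsets, nmd_distance_nt)
        if ptc_pos is not None
        else False
    )
    truncated = ptc_pos is not None and not nmd and len(mut_protein) < len(wt_protein)
    notation = format_notation(
        wt_protein, mut_protein, in_frame=(frame != FrameEffect.FRAMESHIFT), stop_found=stop_found
    )
    if notation == "." and frame == FrameEffect.NONE:
        pass
    return ProteinEffect(
        frame=frame,
        notation=notation,
        ptc_mrna_pos=ptc_pos,
        nmd_predicted=nmd,
        truncated=truncated,
        notes=tuple(notes),
    )
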