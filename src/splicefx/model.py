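"""Coordinate-aware domain types and splice-site geometry.

Everything downstream (signal localization, size arithmetic, transcript
editing) is expressed through these types.  Coordinates are 1-based inclusive
throughout, the VCF/GTF convention; any half-open conversion happens inside
file readers only.

Splice-site anchors follow SpliceAI's labelling: a *donor* is the last exonic
base of the upstream exon (in transcript orientation) and an *acceptor* is the
first exonic base of the downstream exon.  All size arithmetic elsewhere in
the package is stated against these anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Literal, Mapping, Optional, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: SpliceAI reports delta positions within +/-4999 bp of the variant.
ANALYSIS_WINDOW = 4999


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DpConvention(str, Enum):
    """Sign convention for SpliceAI delta positions.

    ``GENOME_FORWARD`` (the default): position = variant pos + dp on either
    strand.  ``STRAND_RELATIVE``: dp is counted along the transcript strand,
    so position = variant pos - dp on the minus strand.
    """

    GENOME_FORWARD = "genome-forward"
    STRAND_RELATIVE = "strand-relative"


class GenomeRef:
    """Reference nucleotide sequence, addressable by 1-based inclusive interval.

    Backed either by an in-memory mapping of contig name -> uppercase sequence
    (toy genomes, tests) or lazily by an indexed FASTA via pyfaidx.
    """

    def __init__(self, contigs: Optional[Mapping[str, str]] = None) -> None:
        self._contigs = {}
        self._fasta = None
        if contigs:
            for name, seq in contigs.items():
                if len(seq) < 1:
                    raise ValueError(f"contig {name!r} has empty sequence")
                self._contigs[name] = seq.upper()

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeRef":
        import pyfaidx

        ref = cls()
        ref._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return ref

    def __contains__(self, contig: str) -> bool:
        if self._fasta is not None:
            return contig in self._fasta
        return contig in self._contigs

    def contig_length(self, contig: str) -> int:
        if self._fasta is not None:
            return len(self._fasta[contig])
        return len(self._contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive; length end-start+1."""
        if start < 1 or end < start:
            raise ValueError(f"bad interval [{start}, {end}]")
        if contig not in self:
            raise KeyError(f"contig {contig!r} not in reference")
        if end > self.contig_length(contig):
            raise ValueError(
                f"interval [{start}, {end}] beyond end of {contig} "
                f"({self.contig_length(contig)} bp)"
            )
        if self._fasta is not None:
            return str(self._fasta[contig][start - 1 : end])
        return self._contigs[contig][start - 1 : end]

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos)


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution. Only SNVs are interpretable:
    delta positions for indels have ambiguous anchor semantics."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not an SNV: {self.ref}>{self.alt}")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref == alt ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.pos} {self.ref}>{self.alt}"


@dataclass(frozen=True)
class SpliceAIRecord:
    """One SNV with the four delta scores and four delta positions for one gene."""

    variant: Variant
    gene_symbol: str
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int

    def __post_init__(self) -> None:
        for name in ("ds_ag", "ds_al", "ds_dg", "ds_dl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("dp_ag", "dp_al", "dp_dg", "dp_dl"):
            v = getattr(self, name)
            if abs(v) > ANALYSIS_WINDOW:
                raise ValueError(f"{name}={v} outside +/-{ANALYSIS_WINDOW} window")


@dataclass(frozen=True)
class Thresholds:
    """Calling thresholds and size bounds.

    ``noise_floor`` — below this a delta score carries no signal at all.
    ``loss_call_threshold`` — native-site losses at or above this drive
    exon skipping and whole intron retention calls.
    ``gain_call_threshold`` — cryptic-site gains at or above this drive
    pseudoexon, partial intron retention and partial exon deletion calls.
    Thresholds are inclusive: score >= threshold fires.
    """

    noise_floor: float = 0.02
    loss_call_threshold: float = 0.2
    gain_call_threshold: float = 0.05
    pseudoexon_min_bp: int = 25
    pseudoexon_max_bp: int = 500
    dp_convention: DpConvention = DpConvention.GENOME_FORWARD
    nmd_distance_nt: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.noise_floor <= self.gain_call_threshold <= 1:
            raise ValueError("require 0 <= noise_floor <= gain_call_threshold <= 1")
        if not 0 <= self.noise_floor <= self.loss_call_threshold <= 1:
            raise ValueError("require 0 <= noise_floor <= loss_call_threshold <= 1")
        if not 0 < self.pseudoexon_min_bp < self.pseudoexon_max_bp:
            raise ValueError("require 0 < pseudoexon_min_bp < pseudoexon_max_bp")
        if self.nmd_distance_nt < 0:
            raise ValueError("nmd_distance_nt must be >= 0")


class SiteKind(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"


@dataclass(frozen=True)
class SpliceSite:
    """A native splice site: the boundary exonic base of an intron.

    ``intron_index`` counts in transcript orientation starting at 1; the donor
    of intron i is the last base of exon i, the acceptor is the first base of
    exon i+1 (exon indices also in transcript orientation).
    """

    kind: SiteKind
    pos: int
    intron_index: int


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one RefSeq transcript on one contig.

    ``exons`` are genomic (start, end) intervals, 1-based inclusive, sorted by
    genomic start and non-overlapping.  ``cds_start``/``cds_end`` bound the
    coding region genomically (cds_start <= cds_end regardless of strand);
    both ``None`` for non-coding transcripts.
    """

    gene_symbol: str
    transcript_id: str
    contig: str
    strand: Literal["+", "-"]
    exons: Sequence[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError("transcript must have >= 1 exon")
        for s, e in exons:
            if s > e:
                raise ValueError(f"exon ({s}, {e}) has start > end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", exons)
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be both set or both None")
        if self.cds_start is not None:
            if self.cds_start > self.cds_end:
                raise ValueError("cds_start must be <= cds_end")
            for pos in (self.cds_start, self.cds_end):
                if self._exonic_index(pos) is None:
                    raise ValueError(f"CDS boundary {pos} not exonic")
            if self.cds_length() < 3:
                raise ValueError("CDS shorter than one codon")

    # ---- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def is_coding(self) -> bool:
        return self.cds_start is not None

    def _exonic_index(self, pos: int) -> Optional[int]:
        """Genomic exon index (0-based) containing pos, else None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    # ---- transcript-orientation views ----------------------------------
    # Transcript exon/intron index 1..n counts along the direction of
    # transcription: on '-' the genomically last exon is exon 1.

    def _tx_to_genomic_exon(self, i: int) -> int:
        if not 1 <= i <= self.n_exons:
            raise IndexError(f"exon index {i} out of range 1..{self.n_exons}")
        return i - 1 if self.strand == "+" else self.n_exons - i

    def tx_exon(self, i: int) -> tuple[int, int]:
        """Genomic (start, end) of transcript-orientation exon i."""
        return self.exons[self._tx_to_genomic_exon(i)]

    def exon_length(self, i: int) -> int:
        s, e = self.tx_exon(i)
        return e - s + 1

    def intron_interval(self, i: int) -> tuple[int, int]:
        """Genomic (start, end) of transcript-orientation intron i."""
        if not 1 <= i <= self.n_introns:
            raise IndexError(f"intron index {i} out of range 1..{self.n_introns}")
        up = self.tx_exon(i)
        down = self.tx_exon(i + 1)
        lo, hi = (up[1] + 1, down[0] - 1) if self.strand == "+" else (down[1] + 1, up[0] - 1)
        return (lo, hi)

    def intron_length(self, i: int) -> int:
        s, e = self.intron_interval(i)
        return e - s + 1

    def donor_site(self, intron_index: int) -> SpliceSite:
        """Last exonic base of exon ``intron_index`` (transcript orientation)."""
        s, e = self.tx_exon(intron_index)
        pos = e if self.strand == "+" else s
        return SpliceSite(SiteKind.DONOR, pos, intron_index)

    def acceptor_site(self, intron_index: int) -> SpliceSite:
        """First exonic base of exon ``intron_index + 1``."""
        s, e = self.tx_exon(intron_index + 1)
        pos = s if self.strand == "+" else e
        return SpliceSite(SiteKind.ACCEPTOR, pos, intron_index)

    def tx_distance(self, a: int, b: int) -> int:
        """Signed distance from a to b along the transcript direction."""
        return b - a if self.strand == "+" else a - b

    def advance(self, pos: int, n: int) -> int:
        """Position n bases downstream of pos in transcript orientation."""
        return pos + n if self.strand == "+" else pos - n

    def locate(self, pos: int) -> tuple[str, Optional[int]]:
        """Classify a genomic position against the transcript.

        Returns ("exon", i) or ("intron", i) with transcript-orientation
        index, or ("outside", None) when beyond the transcript span.
        """
        gi = self._exonic_index(pos)
        if gi is not None:
            i = gi + 1 if self.strand == "+" else self.n_exons - gi
            return ("exon", i)
        lo, hi = self.span
        if not lo <= pos <= hi:
            return ("outside", None)
        for i in range(1, self.n_introns + 1):
            s, e = self.intron_interval(i)
            if s <= pos <= e:
                return ("intron", i)
        return ("outside", None)  # unreachable for valid models

    def cds_length(self) -> int:
        if not self.is_coding():
            return 0
        total = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                total += hi - lo + 1
        return total

    def cds_translation_start(self) -> int:
        """Genomic position of the first base of the start codon."""
        if not self.is_coding():
            raise ValueError("non-coding transcript")
        return self.cds_start if self.strand == "+" else self.cds_end

    def cds_translation_end(self) -> int:
        """Genomic position of the last base of the CDS (stop codon end)."""
        if not self.is_coding():
            raise ValueError("non-coding transcript")
        return self.cds_end if self.strand == "+" else self.cds_start

    def exon_sequence_iter(self) -> Iterator[tuple[int, int]]:
        """Exon intervals in transcript orientation."""
        for i in range(1, self.n_exons + 1):
            yield self.tx_exon(i)


def native_splice_sites(t: TranscriptModel) -> list[SpliceSite]:
    """All native splice sites in transcript orientation.

    For n exons: n-1 donors and n-1 acceptors, ordered donor(1), acceptor(1),
    donor(2), ... A single-exon transcript has none.
    """
    sites: list[SpliceSite] = []
    for i in range(1, t.n_introns + 1):
        sites.append(t.donor_site(i))
        sites.append(t.acceptor_site(i))
    return sites


def resolve_dp(
    v: Variant,
    dp: int,
    strand: Literal["+", "-"],
    convention: DpConvention = DpConvention.GENOME_FORWARD,
) -> int:
    """Map a SpliceAI delta position to a genomic coordinate."""
    if abs(dp) > ANALYSIS_WINDOW:
        raise ValueError(f"delta position {dp} outside +/-{ANALYSIS_WINDOW} window")
    if convention == DpConvention.GENOME_FORWARD:
        return v.pos + dp
    return v.pos + dp if strand == "+" else v.pos - dp
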