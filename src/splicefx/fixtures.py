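"""Deterministic toy genomes, transcripts and forged SpliceAI records.

Every detector and the protein layer are testable without any download: a
case is generated together with its ground truth (expected aberration types,
exact sizes, net length change, frame), computed from the generation
parameters and never from the engine under test.

Forged delta scores carry no sequence-derived meaning — this is not a
splicing-model emulator.  Gains default to 0.60 and losses to 0.90, well
clear of the default calling thresholds (0.05 gain / 0.2 loss); dedicated
edge cases place scores at threshold +/- 0.01 to pin the inclusive (score >=
threshold) boundary semantics.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .io import write_spliceai_vcf
from .model import GenomeRef, SpliceAIRecord, TranscriptModel, Variant, reverse_complement

_STOP_FREE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

GAIN_SCORE = 0.60
LOSS_SCORE = 0.90


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth for one forged case, fixed at generation time."""

    category: str
    types: tuple[str, ...]  # expected aberration types, sorted alphabetically
    inserted_bp: int
    deleted_bp: int
    delta_len: int
    frame: str  # "in_frame" | "frameshift" | "none"
    spliceogenic: bool
    expect_window_limited_note: bool = False


@dataclass(frozen=True)
class FixtureCase:
    name: str
    genome: GenomeRef
    transcript: TranscriptModel
    record: SpliceAIRecord
    truth: FixtureTruth
    seed: int


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _other_base(rng: random.Random, base: str) -> str:
    return rng.choice([b for b in "ACGT" if b != base])


def make_toy_gene(
    n_exons: int = 3,
    exon_len_range: tuple[int, int] = (90, 180),
    intron_len_range: tuple[int, int] = (300, 800),
    seed: int = 0,
    strand: str = "+",
    utr5_len: int = 30,
    utr3_len: int = 30,
    flank: int = 200,
    contig: str = "chrT",
    gene: str = "GENE1",
    transcript: str = "NM_000001.1",
    exon_lens: Optional[Sequence[int]] = None,
    intron_lens: Optional[Sequence[int]] = None,
) -> tuple[GenomeRef, TranscriptModel]:
    """Build a random gene with canonical splice-site dinucleotides.

    Introns begin GT and end AG; the CDS starts with ATG, ends with a stop
    codon, and contains no internal in-frame stop.  Fully reproducible from
    the seed.  Explicit ``exon_lens``/``intron_lens`` override the random
    draws (used to host events of a required size).
    """
    if n_exons < 1:
        raise ValueError("need >= 1 exon")
    rng = random.Random(seed)
    if exon_lens is None:
        exon_lens = [rng.randint(*exon_len_range) for _ in range(n_exons)]
    if intron_lens is None:
        intron_lens = [rng.randint(*intron_len_range) for _ in range(n_exons - 1)]
    if len(exon_lens) != n_exons or len(intron_lens) != n_exons - 1:
        raise ValueError("exon/intron length lists inconsistent with n_exons")
    if any(l < 10 for l in intron_lens):
        raise ValueError("introns must be >= 10 bp")
    total_exonic = sum(exon_lens)
    coding_len = total_exonic - utr5_len - utr3_len
    coding_len -= coding_len % 3
    if coding_len < 6:
        raise ValueError("exons too short for the requested UTRs plus a CDS")
    if exon_lens[0] <= utr5_len + 3 or exon_lens[-1] <= total_exonic - utr5_len - coding_len + 3:
        raise ValueError("terminal exons too short for the UTRs")

    n_mid = coding_len // 3 - 2
    cds = "ATG" + "".join(rng.choice(_STOP_FREE_CODONS) for _ in range(n_mid)) + "TAA"
    exonic = _random_seq(rng, utr5_len) + cds
    exonic += _random_seq(rng, total_exonic - len(exonic))

    pieces: list[str] = [_random_seq(rng, flank)]
    exon_coords: list[tuple[int, int]] = []
    pos = flank
    off = 0
    for i, elen in enumerate(exon_lens):
        exon_coords.append((pos + 1, pos + elen))
        pieces.append(exonic[off : off + elen])
        off += elen
        pos += elen
        if i < n_exons - 1:
            ilen = intron_lens[i]
            pieces.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            pos += ilen
    pieces.append(_random_seq(rng, flank))
    seq = "".join(pieces)

    cds_start = _exonic_offset_to_genomic(exon_coords, utr5_len)
    cds_end = _exonic_offset_to_genomic(exon_coords, utr5_len + coding_len - 1)

    genome = GenomeRef({contig: seq})
    model = TranscriptModel(
        gene_symbol=gene,
        transcript_id=transcript,
        contig=contig,
        strand="+",
        exons=exon_coords,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    if strand == "-":
        genome, model = mirror_gene(genome, model)
    return genome, model


def _exonic_offset_to_genomic(exons: Sequence[tuple[int, int]], off: int) -> int:
    for s, e in exons:
        n = e - s + 1
        if off < n:
            return s + off
        off -= n
    raise ValueError("offset beyond exonic length")


def mirror_gene(
    genome: GenomeRef, t: TranscriptModel
) -> tuple[GenomeRef, TranscriptModel]:
    """Reverse-complement the contig and flip the transcript to the other strand.

    Transcript-orientation structure (exon order, splice-site roles, CDS) is
    preserved; only genomic coordinates change.
    """
    seq = genome.fetch(t.contig, 1, genome.contig_length(t.contig))
    L = len(seq)
    mirrored = GenomeRef({t.contig: reverse_complement(seq)})
    exons = sorted((L - e + 1, L - s + 1) for s, e in t.exons)
    model = TranscriptModel(
        gene_symbol=t.gene_symbol,
        transcript_id=t.transcript_id,
        contig=t.contig,
        strand="-" if t.strand == "+" else "+",
        exons=exons,
        cds_start=None if t.cds_start is None else L - t.cds_end + 1,
        cds_end=None if t.cds_end is None else L - t.cds_start + 1,
    )
    return mirrored, model


def mirror_case(case: FixtureCase) -> FixtureCase:
    """The same case seen from the opposite strand (genome-forward dp flips sign)."""
    genome, model = mirror_gene(case.genome, case.transcript)
    L = genome.contig_length(model.contig)
    v = case.record.variant
    comp = str.maketrans("ACGT", "TGCA")
    variant = Variant(v.contig, L - v.pos + 1, v.ref.translate(comp), v.alt.translate(comp))
    r = case.record
    record = SpliceAIRecord(
        variant=variant,
        gene_symbol=r.gene_symbol,
        ds_ag=r.ds_ag,
        ds_al=r.ds_al,
        ds_dg=r.ds_dg,
        ds_dl=r.ds_dl,
        dp_ag=-r.dp_ag,
        dp_al=-r.dp_al,
        dp_dg=-r.dp_dg,
        dp_dl=-r.dp_dl,
    )
    return FixtureCase(case.name + "_mirrored", genome, model, record, case.truth, case.seed)


# ---------------------------------------------------------------------------
# forging


def _frame_of(delta: int) -> str:
    if delta == 0:
        return "none"
    return "in_frame" if delta % 3 == 0 else "frameshift"


def _record(
    genome: GenomeRef,
    t: TranscriptModel,
    variant_pos: int,
    rng: random.Random,
    sites: dict[str, int],
    scores: dict[str, float],
) -> SpliceAIRecord:
    """Assemble a record; dp values are genome-forward offsets to the sites."""
    ref = genome.base(t.contig, variant_pos)
    variant = Variant(t.contig, variant_pos, ref, _other_base(rng, ref))

    def dp(key: str) -> int:
        pos = sites.get(key)
        if pos is None:
            return 0
        d = pos - variant_pos
        if abs(d) > 4999:
            raise ValueError(f"site {key} at {pos} outside the window of {variant_pos}")
        return d

    return SpliceAIRecord(
        variant=variant,
        gene_symbol=t.gene_symbol,
        ds_ag=scores.get("ag", 0.0),
        ds_al=scores.get("al", 0.0),
        ds_dg=scores.get("dg", 0.0),
        ds_dl=scores.get("dl", 0.0),
        dp_ag=dp("ag"),
        dp_al=dp("al"),
        dp_dg=dp("dg"),
        dp_dl=dp("dl"),
    )


def forge_case(
    aberration_type: str,
    params: Optional[dict] = None,
    seed: int = 0,
) -> FixtureCase:
    """Forge one case whose ground truth is the requested aberration.

    ``aberration_type`` is one of: pseudoexonization,
    partial_intron_retention_donor, partial_intron_retention_acceptor,
    partial_exon_deletion_donor, partial_exon_deletion_acceptor,
    exon_skipping, multi_exon_skipping, whole_intron_retention,
    combination_skip_retention, window_limited, negative.

    ``params`` may override: size, strand, gain_score, loss_score, name,
    gene, transcript, contig.
    """
    p = dict(params or {})
    rng = random.Random(seed)
    strand = p.get("strand", "+")
    gain = p.get("gain_score", GAIN_SCORE)
    loss = p.get("loss_score", LOSS_SCORE)
    name = p.get("name", f"{aberration_type}_{seed}")
    ids = {
        "contig": p.get("contig", f"chr_{name}"),
        "gene": p.get("gene", f"GENE_{name}"),
        "transcript": p.get("transcript", f"NM_{seed:06d}.1"),
    }
    builder = _FORGERS.get(aberration_type)
    if builder is None:
        raise ValueError(f"unknown aberration type {aberration_type!r}")
    return builder(p, rng, strand, gain, loss, name, ids, seed)


def _gene(seed, strand, ids, rng, **kw) -> tuple[GenomeRef, TranscriptModel]:
    return make_toy_gene(
        seed=rng.randrange(2**31),
        strand=strand,
        contig=ids["contig"],
        gene=ids["gene"],
        transcript=ids["transcript"],
        **kw,
    )


def _forge_pseudoexon(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    size = p.get("size", rng.randint(25, 500))
    intron_len = size + rng.randint(60, 160)
    genome, t = _gene(
        seed, strand, ids, rng, n_exons=3, intron_lens=[intron_len, intron_len]
    )
    intron = p.get("intron", rng.randint(1, 2))
    donor = t.donor_site(intron).pos
    offset = rng.randint(5, intron_len - size - 5)
    ag_pos = t.advance(donor, offset)
    dg_pos = t.advance(ag_pos, size - 1)
    var_pos = t.advance(ag_pos, size // 2)
    record = _record(genome, t, var_pos, rng, {"ag": ag_pos, "dg": dg_pos}, {"ag": gain, "dg": gain})
    in_range = 25 <= size <= 500
    truth = FixtureTruth(
        category="pseudoexonization",
        types=("pseudoexonization",) if in_range else ("no_impact",),
        inserted_bp=size if in_range else 0,
        deleted_bp=0,
        delta_len=size if in_range else 0,
        frame=_frame_of(size) if in_range else "none",
        spliceogenic=in_range,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


def _forge_pir(side):
    def build(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
        size = p.get("size", rng.randint(5, 200))
        intron_len = max(300, size + rng.randint(30, 120))
        genome, t = _gene(
            seed, strand, ids, rng, n_exons=3, intron_lens=[intron_len, intron_len]
        )
        intron = p.get("intron", rng.randint(1, 2))
        if side == "donor":
            anchor = t.donor_site(intron).pos
            gain_pos = t.advance(anchor, size)
            key = "dg"
        else:
            anchor = t.acceptor_site(intron).pos
            gain_pos = t.advance(anchor, -size)
            key = "ag"
        var_pos = t.advance(gain_pos, -(size // 2)) if side == "donor" else t.advance(
            gain_pos, size // 2
        )
        record = _record(genome, t, var_pos, rng, {key: gain_pos}, {key: gain})
        truth = FixtureTruth(
            category=f"partial_intron_retention_{side}",
            types=("partial_intron_retention",),
            inserted_bp=size,
            deleted_bp=0,
            delta_len=size,
            frame=_frame_of(size),
            spliceogenic=True,
        )
        return FixtureCase(name, genome, t, record, truth, seed)

    return build


def _forge_ped(side):
    def build(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
        genome, t = _gene(seed, strand, ids, rng, n_exons=3, exon_len_range=(120, 200))
        exon = 2
        elen = t.exon_length(exon)
        size = p.get("size", rng.randint(5, elen - 10))
        if size > elen - 1:
            raise ValueError("deletion larger than the exon")
        if side == "donor":
            anchor = t.donor_site(exon).pos
            gain_pos = t.advance(anchor, -size)
            key = "dg"
            var_pos = t.advance(gain_pos, max(1, size // 2))
        else:
            anchor = t.acceptor_site(exon - 1).pos
            gain_pos = t.advance(anchor, size)
            key = "ag"
            var_pos = t.advance(anchor, size // 2)
        record = _record(genome, t, var_pos, rng, {key: gain_pos}, {key: gain})
        truth = FixtureTruth(
            category=f"partial_exon_deletion_{side}",
            types=("partial_exon_deletion",),
            inserted_bp=0,
            deleted_bp=size,
            delta_len=-size,
            frame=_frame_of(-size),
            spliceogenic=True,
        )
        return FixtureCase(name, genome, t, record, truth, seed)

    return build


def _forge_exon_skipping(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    n_exons = p.get("n_exons", 4)
    genome, t = _gene(seed, strand, ids, rng, n_exons=n_exons)
    exon = p.get("exon", rng.randint(2, n_exons - 1))
    acc = t.acceptor_site(exon - 1).pos
    don = t.donor_site(exon).pos
    var_pos = t.advance(acc, t.exon_length(exon) // 2)
    record = _record(
        genome, t, var_pos, rng, {"al": acc, "dl": don}, {"al": loss, "dl": loss}
    )
    deleted = t.exon_length(exon)
    truth = FixtureTruth(
        category="exon_skipping",
        types=("exon_skipping",),
        inserted_bp=0,
        deleted_bp=deleted,
        delta_len=-deleted,
        frame=_frame_of(-deleted),
        spliceogenic=True,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


def _forge_multi_exon_skipping(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    n_exons = 5
    genome, t = _gene(
        seed, strand, ids, rng, n_exons=n_exons, intron_len_range=(200, 500)
    )
    e1 = p.get("e1", rng.randint(2, 3))
    e2 = p.get("e2", e1 + 1)
    acc = t.acceptor_site(e1 - 1).pos
    don = t.donor_site(e2).pos
    # variant inside the skipped range keeps both losses within the window
    var_pos = t.advance(t.donor_site(e1).pos, t.intron_length(e1) // 2)
    record = _record(
        genome, t, var_pos, rng, {"al": acc, "dl": don}, {"al": loss, "dl": loss}
    )
    deleted = sum(t.exon_length(e) for e in range(e1, e2 + 1))
    truth = FixtureTruth(
        category="multi_exon_skipping",
        types=("multi_exon_skipping",),
        inserted_bp=0,
        deleted_bp=deleted,
        delta_len=-deleted,
        frame=_frame_of(-deleted),
        spliceogenic=True,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


def _forge_whole_intron_retention(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    genome, t = _gene(seed, strand, ids, rng, n_exons=3, intron_len_range=(200, 900))
    intron = p.get("intron", rng.randint(1, 2))
    don = t.donor_site(intron).pos
    acc = t.acceptor_site(intron).pos
    var_pos = t.advance(don, t.intron_length(intron) // 2)
    record = _record(
        genome, t, var_pos, rng, {"al": acc, "dl": don}, {"al": loss, "dl": loss}
    )
    inserted = t.intron_length(intron)
    truth = FixtureTruth(
        category="whole_intron_retention",
        types=("whole_intron_retention",),
        inserted_bp=inserted,
        deleted_bp=0,
        delta_len=inserted,
        frame=_frame_of(inserted),
        spliceogenic=True,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


def _forge_combination(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    """Exon skipping of an internal exon plus a donor-side retention of intron 1."""
    genome, t = _gene(seed, strand, ids, rng, n_exons=4, intron_len_range=(200, 400))
    exon = 3
    size = p.get("size", rng.randint(5, 150))
    acc = t.acceptor_site(exon - 1).pos
    don = t.donor_site(exon).pos
    gain_pos = t.advance(t.donor_site(1).pos, size)
    var_pos = t.advance(t.acceptor_site(1).pos, 5)  # in exon 2, between the events
    record = _record(
        genome,
        t,
        var_pos,
        rng,
        {"al": acc, "dl": don, "dg": gain_pos},
        {"al": loss, "dl": loss, "dg": gain},
    )
    deleted = t.exon_length(exon)
    truth = FixtureTruth(
        category="combination_skip_retention",
        types=tuple(sorted(("exon_skipping", "partial_intron_retention"))),
        inserted_bp=size,
        deleted_bp=deleted,
        delta_len=size - deleted,
        frame=_frame_of(size - deleted),
        spliceogenic=True,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


def _forge_window_limited(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    """A lone donor loss whose partner acceptor lies beyond the 10 kb window."""
    intron_len = p.get("intron_len", 6000)
    genome, t = _gene(seed, strand, ids, rng, n_exons=3, intron_lens=[intron_len, 300])
    don = t.donor_site(1).pos
    var_pos = t.advance(don, 200)  # deep in the long intron, near its donor
    record = _record(genome, t, var_pos, rng, {"dl": don}, {"dl": loss})
    truth = FixtureTruth(
        category="window_limited",
        types=("no_impact",),
        inserted_bp=0,
        deleted_bp=0,
        delta_len=0,
        frame="none",
        spliceogenic=False,
        expect_window_limited_note=True,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


def _forge_negative(p, rng, strand, gain, loss, name, ids, seed) -> FixtureCase:
    genome, t = _gene(seed, strand, ids, rng, n_exons=3)
    span = t.span
    var_pos = rng.randint(span[0], span[1])
    ref = genome.base(t.contig, var_pos)
    variant = Variant(t.contig, var_pos, ref, _other_base(rng, ref))
    record = SpliceAIRecord(
        variant=variant,
        gene_symbol=t.gene_symbol,
        ds_ag=round(rng.uniform(0.0, 0.01), 2),
        ds_al=round(rng.uniform(0.0, 0.01), 2),
        ds_dg=round(rng.uniform(0.0, 0.01), 2),
        ds_dl=round(rng.uniform(0.0, 0.01), 2),
        dp_ag=rng.randint(-300, 300),
        dp_al=rng.randint(-300, 300),
        dp_dg=rng.randint(-300, 300),
        dp_dl=rng.randint(-300, 300),
    )
    truth = FixtureTruth(
        category="negative",
        types=("no_impact",),
        inserted_bp=0,
        deleted_bp=0,
        delta_len=0,
        frame="none",
        spliceogenic=False,
    )
    return FixtureCase(name, genome, t, record, truth, seed)


_FORGERS = {
    "pseudoexonization": _forge_pseudoexon,
    "partial_intron_retention_donor": _forge_pir("donor"),
    "partial_intron_retention_acceptor": _forge_pir("acceptor"),
    "partial_exon_deletion_donor": _forge_ped("donor"),
    "partial_exon_deletion_acceptor": _forge_ped("acceptor"),
    "exon_skipping": _forge_exon_skipping,
    "multi_exon_skipping": _forge_multi_exon_skipping,
    "whole_intron_retention": _forge_whole_intron_retention,
    "combination_skip_retention": _forge_combination,
    "window_limited": _forge_window_limited,
    "negative": _forge_negative,
}

CATEGORIES = tuple(_FORGERS)


def build_corpus(seed: int, n_per_type: int = 30) -> list[FixtureCase]:
    """A balanced forged corpus: ``n_per_type`` cases per category.

    Strands alternate between cases; generation is bit-identical for a fixed
    (seed, n_per_type).
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    cases = []
    idx = 0
    for category in CATEGORIES:
        for k in range(n_per_type):
            child = (seed * 100003 + idx * 7919 + 17) % (2**31)
            strand = "+" if k % 2 == 0 else "-"
            cases.append(
                forge_case(
                    category,
                    {
                        "strand": strand,
                        "name": f"case{idx:04d}_{category}",
                        "contig": f"ctg{idx:04d}",
                        "gene": f"GENE{idx:04d}",
                        "transcript": f"NM_{idx:06d}.1",
                    },
                    seed=child,
                )
            )
            idx += 1
    return cases


# ---------------------------------------------------------------------------
# file emission (the exact formats the main tool reads)


def write_corpus_files(cases: Sequence[FixtureCase], outdir: str | Path) -> dict[str, Path]:
    """Emit the corpus as FASTA + GTF + gene table + SpliceAI VCF + label TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "annotation.gtf",
        "genes": out / "genes.tsv",
        "vcf": out / "variants.vcf",
        "labels": out / "labels.tsv",
    }

    with paths["fasta"].open("w") as fh:
        for case in cases:
            contig = case.transcript.contig
            seq = case.genome.fetch(contig, 1, case.genome.contig_length(contig))
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with paths["gtf"].open("w") as fh:
        for case in cases:
            fh.write(transcript_to_gtf(case.transcript))

    with paths["genes"].open("w") as fh:
        fh.write("gene\ttranscript\n")
        for case in cases:
            fh.write(f"{case.transcript.gene_symbol}\t{case.transcript.transcript_id}\n")

    write_spliceai_vcf(
        [c.record for c in cases],
        paths["vcf"],
        {c.transcript.contig: c.genome.contig_length(c.transcript.contig) for c in cases},
    )

    with paths["labels"].open("w") as fh:
        fh.write(
            "variant\tgene\tcategory\tspliceogenic\taberration_types\t"
            "inserted_bp\tdeleted_bp\tframe_effect\n"
        )
        for case in cases:
            tr = case.truth
            fh.write(
                "\t".join(
                    [
                        case.record.variant.id,
                        case.transcript.gene_symbol,
                        tr.category,
                        "yes" if tr.spliceogenic else "no",
                        ";".join(tr.types),
                        str(tr.inserted_bp),
                        str(tr.deleted_bp),
                        tr.frame,
                    ]
                )
                + "\n"
            )
    return paths


def transcript_to_gtf(t: TranscriptModel) -> str:
    """GTF lines for one transcript (exon + CDS features; CDS includes the stop)."""
    attrs = (
        f'gene_id "{t.gene_symbol}"; transcript_id "{t.transcript_id}"; '
        f'gene_name "{t.gene_symbol}";'
    )
    lines = []
    for s, e in t.exons:
        lines.append(
            f"{t.contig}\ttoy\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
        )
        if t.is_coding():
            lo, hi = max(s, t.cds_start), min(e, t.cds_end)
            if lo <= hi:
                lines.append(
                    f"{t.contig}\ttoy\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t0\t{attrs}\n"
                )
    return "".join(lines)
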