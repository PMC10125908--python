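"""Readers and writers for the formats the calculator touches.

Input: a SpliceAI-annotated VCF (pysam), a gene -> RefSeq transcript table
(TSV), a transcript annotation (GTF/GFF3 via gffutils, or refFlat), and a
genome FASTA (pyfaidx, through :class:`~splicefx.model.GenomeRef`).  Output:
a tab-separated results table with one row per (variant, gene) pair.

GTF/GFF3 coordinates are 1-based inclusive and used as-is; refFlat starts are
0-based half-open and converted at read time.  Unknown/NA values serialize
as ".".
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

from .model import SpliceAIRecord, TranscriptModel, Variant

logger = logging.getLogger("splicefx")

SPLICEAI_INFO_KEY = "SpliceAI"
_SPLICEAI_ARITY = 10  # ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL

_ACCESSION_RE = re.compile(r"^[A-Z]{2}_[0-9]+(\.[0-9]+)?$|^ENST[0-9]+(\.[0-9]+)?$")


# ---------------------------------------------------------------------------
# SpliceAI VCF


@dataclass
class VcfParseResult:
    """Parsed records plus the skip/error bookkeeping the run report needs."""

    records: list[SpliceAIRecord] = field(default_factory=list)
    n_rows: int = 0
    skipped_non_snv: int = 0
    skipped_no_annotation: int = 0
    row_errors: list[str] = field(default_factory=list)


def parse_spliceai_vcf(path: str | Path) -> VcfParseResult:
    """Read a SpliceAI-annotated VCF into one record per (variant, gene) pair.

    Multi-allelic rows are split per alternate allele; SpliceAI annotations
    are matched to their allele.  Rows that are not SNVs, or that lack the
    SpliceAI INFO key, are skipped with a warning and counted.  A malformed
    annotation is collected as a per-row error and parsing continues.
    """
    result = VcfParseResult()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            result.n_rows += 1
            annotations = _spliceai_annotations(rec)
            if annotations is None:
                result.skipped_no_annotation += 1
                logger.warning(
                    "no %s annotation at %s:%d", SPLICEAI_INFO_KEY, rec.contig, rec.pos
                )
                continue
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt in ("*", "<NON_REF>"):
                    result.skipped_non_snv += 1
                    logger.warning(
                        "skipping non-SNV %s:%d %s>%s", rec.contig, rec.pos, rec.ref, alt
                    )
                    continue
                for ann in annotations:
                    parsed = _parse_annotation(ann, rec, alt, result.row_errors)
                    if parsed is not None:
                        result.records.append(parsed)
    return result


def _spliceai_annotations(rec) -> Optional[list[str]]:
    if SPLICEAI_INFO_KEY not in rec.info:
        return None
    value = rec.info[SPLICEAI_INFO_KEY]
    if isinstance(value, str):
        return value.split(",")
    return [str(v) for v in value]


def _parse_annotation(
    ann: str, rec, alt: str, errors: list[str]
) -> Optional[SpliceAIRecord]:
    fields = ann.split("|")
    where = f"{rec.contig}:{rec.pos}"
    if len(fields) != _SPLICEAI_ARITY:
        errors.append(f"{where}: annotation has {len(fields)} fields, expected {_SPLICEAI_ARITY}")
        return None
    if fields[0] != alt:
        return None  # annotation belongs to a different allele of this row
    try:
        variant = Variant(rec.contig, rec.pos, rec.ref, alt)
        return SpliceAIRecord(
            variant=variant,
            gene_symbol=fields[1],
            ds_ag=float(fields[2]),
            ds_al=float(fields[3]),
            ds_dg=float(fields[4]),
            ds_dl=float(fields[5]),
            dp_ag=int(fields[6]),
            dp_al=int(fields[7]),
            dp_dg=int(fields[8]),
            dp_dl=int(fields[9]),
        )
    except ValueError as exc:
        errors.append(f"{where}: {exc}")
        return None


def spliceai_info_value(r: SpliceAIRecord) -> str:
    """Serialize one record back to the SpliceAI INFO annotation string."""
    return "|".join(
        [
            r.variant.alt,
            r.gene_symbol,
            f"{r.ds_ag:.2f}",
            f"{r.ds_al:.2f}",
            f"{r.ds_dg:.2f}",
            f"{r.ds_dl:.2f}",
            str(r.dp_ag),
            str(r.dp_al),
            str(r.dp_dg),
            str(r.dp_dl),
        ]
    )


def write_spliceai_vcf(
    records: Sequence[SpliceAIRecord],
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write records as a minimal SpliceAI-annotated VCF (plain text)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SpliceAI,Number=.,Type=String,Description="SpliceAIv1.3.1 variant '
        "annotation. These include delta scores (DS) and delta positions (DP) for "
        "acceptor gain (AG), acceptor loss (AL), donor gain (DG), and donor loss (DL). "
        'Format: ALLELE|SYMBOL|DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL">',
    ]
    for contig, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        v = r.variant
        lines.append(
            f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
            f"{SPLICEAI_INFO_KEY}={spliceai_info_value(r)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene -> transcript table


@dataclass(frozen=True)
class GeneTranscriptTable:
    """Gene symbol -> RefSeq transcript ID, one transcript per gene."""

    mapping: dict[str, str]

    def transcript_for(self, gene: str) -> Optional[str]:
        return self.mapping.get(gene)

    def __len__(self) -> int:
        return len(self.mapping)

    def __iter__(self):
        return iter(self.mapping.items())


def read_gene_transcript_table(path: str | Path) -> GeneTranscriptTable:
    """Read the two-column gene/transcript TSV; a header line is auto-detected.

    Duplicate gene symbols keep the last row, with a warning.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty gene/transcript table: {path}")
    rows = [ln.split("\t") for ln in lines]
    start = 0
    first = rows[0]
    if len(first) >= 2 and not _ACCESSION_RE.match(first[1].strip()):
        start = 1  # header row
    mapping: dict[str, str] = {}
    for row in rows[start:]:
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ValueError(f"malformed gene/transcript row: {row!r}")
        gene, transcript = row[0].strip(), row[1].strip()
        if gene in mapping:
            logger.warning("duplicate gene %s in table; keeping last entry", gene)
        mapping[gene] = transcript
    if not mapping:
        raise ValueError(f"no data rows in gene/transcript table: {path}")
    return GeneTranscriptTable(mapping)


# ---------------------------------------------------------------------------
# transcript annotation (GTF / GFF3 / refFlat)


def load_transcripts(
    annotation_path: str | Path, table: GeneTranscriptTable
) -> tuple[dict[str, TranscriptModel], list[str]]:
    """Materialize the requested transcripts from an annotation file.

    The dialect is auto-detected (extension, then first data line).  Returns
    (gene -> TranscriptModel, list of requested-but-absent transcript IDs).
    A transcript without CDS features loads as non-coding; protein prediction
    is disabled downstream for that gene.
    """
    path = Path(annotation_path)
    if _looks_like_refflat(path):
        found = _load_refflat(path)
    else:
        found = _load_gtf_gff(path)
    out: dict[str, TranscriptModel] = {}
    missing: list[str] = []
    for gene, tid in table:
        key = (gene, _strip_version(tid))
        model = found.get(key) or found.get((None, _strip_version(tid)))
        if model is None:
            missing.append(tid)
            logger.warning("transcript %s (gene %s) absent from annotation", tid, gene)
            continue
        out[gene] = TranscriptModel(
            gene_symbol=gene,
            transcript_id=tid,
            contig=model.contig,
            strand=model.strand,
            exons=model.exons,
            cds_start=model.cds_start,
            cds_end=model.cds_end,
        )
    return out, missing


def _strip_version(tid: str) -> str:
    return tid.split(".")[0]


def _looks_like_refflat(path: Path) -> bool:
    name = path.name.lower()
    if name.endswith((".gtf", ".gff", ".gff3", ".gtf.gz", ".gff.gz", ".gff3.gz")):
        return False
    if "refflat" in name:
        return True
    opener = gzip.open if name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            # refFlat: 11 columns, exon starts/ends as comma lists
            return len(fields) == 11 and fields[9].rstrip(",").replace(",", "").isdigit()
    return False


def _load_refflat(path: Path) -> dict[tuple, TranscriptModel]:
    found: dict[tuple, TranscriptModel] = {}
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gene, tid, contig, strand = f[0], f[1], f[2], f[3]
            cds_start0, cds_end = int(f[6]), int(f[7])
            starts = [int(x) + 1 for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = sorted(zip(starts, ends))
            coding = cds_end > cds_start0
            model = TranscriptModel(
                gene_symbol=gene,
                transcript_id=tid,
                contig=contig,
                strand=strand,
                exons=exons,
                cds_start=cds_start0 + 1 if coding else None,
                cds_end=cds_end if coding else None,
            )
            found[(gene, _strip_version(tid))] = model
            found[(None, _strip_version(tid))] = model
    return found


def _load_gtf_gff(path: Path) -> dict[tuple, TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = _feature_transcript_id(feat)
        if tid is None:
            continue
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [None])[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        bucket = exons if feat.featuretype == "exon" else cds
        bucket.setdefault(tid, []).append((feat.start, feat.end))
    found: dict[tuple, TranscriptModel] = {}
    for tid, intervals in exons.items():
        gene, contig, strand = meta[tid]
        cds_intervals = cds.get(tid)
        cds_start = min(s for s, _ in cds_intervals) if cds_intervals else None
        cds_end = max(e for _, e in cds_intervals) if cds_intervals else None
        model = TranscriptModel(
            gene_symbol=gene or "",
            transcript_id=tid,
            contig=contig,
            strand=strand,
            exons=sorted(intervals),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        found[(gene, _strip_version(tid))] = model
        found[(None, _strip_version(tid))] = model
    return found


def _feature_transcript_id(feat) -> Optional[str]:
    for key in ("transcript_id", "Parent"):
        vals = feat.attributes.get(key)
        if vals:
            v = vals[0]
            return v.split(":", 1)[1] if v.startswith("transcript:") else v
    return None


# ---------------------------------------------------------------------------
# results table


RESULT_COLUMNS = [
    "variant",
    "gene",
    "transcript",
    "aberration_types",
    "inserted_bp",
    "deleted_bp",
    "frame_effect",
    "protein_notation",
    "nmd_predicted",
    "truncated",
    "qualifiers",
    "ds_ag",
    "ds_al",
    "ds_dg",
    "ds_dl",
    "dp_ag",
    "dp_al",
    "dp_dg",
    "dp_dl",
]

NA = "."


@dataclass(frozen=True)
class ResultRow:
    """One output line: the full prediction for one (variant, gene) pair."""

    variant_id: str
    gene: str
    transcript: str = NA
    aberration_types: tuple[str, ...] = ()
    inserted_bp: int = 0
    deleted_bp: int = 0
    frame: str = "none"
    protein_notation: str = NA
    nmd_predicted: Optional[bool] = None
    truncated: Optional[bool] = None
    qualifiers: tuple[str, ...] = ()
    ds_ag: Optional[float] = None
    ds_al: Optional[float] = None
    ds_dg: Optional[float] = None
    ds_dl: Optional[float] = None
    dp_ag: Optional[int] = None
    dp_al: Optional[int] = None
    dp_dg: Optional[int] = None
    dp_dl: Optional[int] = None

    def __post_init__(self) -> None:
        if self.inserted_bp < 0 or self.deleted_bp < 0:
            raise ValueError("sizes must be >= 0")
        if self.frame not in ("in_frame", "frameshift", "none"):
            raise ValueError(f"bad frame effect {self.frame!r}")

    def to_fields(self) -> list[str]:
        def fmt(v) -> str:
            if v is None or v == () or v == "":
                return NA
            if isinstance(v, bool):
                return "yes" if v else "no"
            if isinstance(v, float):
                return f"{v:.2f}"
            if isinstance(v, tuple):
                return ";".join(v)
            return str(v)

        return [
            fmt(self.variant_id),
            fmt(self.gene),
            fmt(self.transcript),
            fmt(self.aberration_types),
            fmt(self.inserted_bp),
            fmt(self.deleted_bp),
            fmt(self.frame),
            fmt(self.protein_notation),
            fmt(self.nmd_predicted),
            fmt(self.truncated),
            fmt(self.qualifiers),
            fmt(self.ds_ag),
            fmt(self.ds_al),
            fmt(self.ds_dg),
            fmt(self.ds_dl),
            fmt(self.dp_ag),
            fmt(self.dp_al),
            fmt(self.dp_dg),
            fmt(self.dp_dl),
        ]


def write_results(rows: Iterable[ResultRow], path: str | Path) -> None:
    """Write the output TSV: fixed column order, header line, input row order."""
    out = Path(path)
    with out.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row.to_fields()) + "\n")
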