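"""End-to-end runs: annotate a VCF, benchmark predictions, emit fixtures.

These are the library-level entry points behind the command-line interface;
they do all the work and return plain data (result rows, report dicts) so
they are directly usable from Python.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import effect as fx
from .engine import AberrationType, classify
from .io import (
    GeneTranscriptTable,
    ResultRow,
    VcfParseResult,
    load_transcripts,
    parse_spliceai_vcf,
    read_gene_transcript_table,
    write_results,
)
from .model import GenomeRef, SpliceAIRecord, Thresholds, TranscriptModel

logger = logging.getLogger("splicefx")


@dataclass
class RunConfig:
    """Paths and tunables for one annotate run."""

    vcf: Path
    genes: Path
    annotation: Path
    fasta: Path
    out: Path
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        for name in ("vcf", "genes", "annotation", "fasta"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def annotate_record(
    record: SpliceAIRecord,
    transcript: TranscriptModel,
    genome: GenomeRef,
    thresholds: Optional[Thresholds] = None,
) -> ResultRow:
    """Classify one (variant, gene) pair and summarize the consequence."""
    th = thresholds or Thresholds()
    calls = classify(record, transcript, th)
    real = [c for c in calls if c.type != AberrationType.NO_IMPACT]
    types = tuple(sorted(c.type.value for c in real)) if real else ("no_impact",)
    inserted = sum(c.inserted_bp for c in real)
    deleted = sum(c.deleted_bp for c in real)
    qualifiers = []
    for c in calls:
        qualifiers.extend(c.notes)
        if c.window_limited:
            qualifiers.append(f"window-limited:{c.type.value}")

    frame = "none"
    notation = "."
    nmd: Optional[bool] = None
    truncated: Optional[bool] = None
    if real and transcript.is_coding():
        try:
            altered = fx.apply_calls(transcript, real, genome, record.variant)
            protein = fx.predict_protein_effect(
                transcript, altered, genome, th.nmd_distance_nt
            )
            frame = protein.frame.value
            notation = protein.notation
            nmd = protein.nmd_predicted
            truncated = protein.truncated
            qualifiers.extend(protein.notes)
        except fx.ConsistencyError as exc:
            qualifiers.append(f"effect-error:{exc}")
    elif real:
        qualifiers.append("non-coding-transcript")

    return ResultRow(
        variant_id=record.variant.id,
        gene=record.gene_symbol,
        transcript=transcript.transcript_id,
        aberration_types=types,
        inserted_bp=inserted,
        deleted_bp=deleted,
        frame=frame,
        protein_notation=notation,
        nmd_predicted=nmd,
        truncated=truncated,
        qualifiers=tuple(dict.fromkeys(qualifiers)),
        ds_ag=record.ds_ag,
        ds_al=record.ds_al,
        ds_dg=record.ds_dg,
        ds_dl=record.ds_dl,
        dp_ag=record.dp_ag,
        dp_al=record.dp_al,
        dp_dg=record.dp_dg,
        dp_dl=record.dp_dl,
    )


def run_annotate(config: RunConfig) -> dict:
    """Annotate every (variant, gene) pair in the VCF; write the output TSV.

    Returns the run report: input/skip counts, per-type call counts, and the
    thresholds that were applied.
    """
    config.validate()
    th = config.thresholds
    parsed: VcfParseResult = parse_spliceai_vcf(config.vcf)
    table: GeneTranscriptTable = read_gene_transcript_table(config.genes)
    transcripts, missing = load_transcripts(config.annotation, table)
    genome = GenomeRef.from_fasta(str(config.fasta))

    rows: list[ResultRow] = []
    type_counts: Counter = Counter()
    n_no_transcript = 0
    for record in parsed.records:
        transcript = transcripts.get(record.gene_symbol)
        if transcript is None:
            n_no_transcript += 1
            reason = (
                "no-transcript-in-annotation"
                if table.transcript_for(record.gene_symbol)
                else "gene-not-in-table"
            )
            rows.append(
                ResultRow(
                    variant_id=record.variant.id,
                    gene=record.gene_symbol,
                    qualifiers=(reason,),
                    ds_ag=record.ds_ag,
                    ds_al=record.ds_al,
                    ds_dg=record.ds_dg,
                    ds_dl=record.ds_dl,
                    dp_ag=record.dp_ag,
                    dp_al=record.dp_al,
                    dp_dg=record.dp_dg,
                    dp_dl=record.dp_dl,
                )
            )
            continue
        row = annotate_record(record, transcript, genome, th)
        for t in row.aberration_types:
            type_counts[t] += 1
        rows.append(row)

    write_results(rows, config.out)
    report = {
        "vcf_rows": parsed.n_rows,
        "records": len(parsed.records),
        "skipped_non_snv": parsed.skipped_non_snv,
        "skipped_no_annotation": parsed.skipped_no_annotation,
        "row_errors": list(parsed.row_errors),
        "missing_transcripts": missing,
        "no_transcript_rows": n_no_transcript,
        "output_rows": len(rows),
        "calls_per_type": dict(sorted(type_counts.items())),
        "thresholds": {
            "noise_floor": th.noise_floor,
            "loss_call_threshold": th.loss_call_threshold,
            "gain_call_threshold": th.gain_call_threshold,
            "pseudoexon_min_bp": th.pseudoexon_min_bp,
            "pseudoexon_max_bp": th.pseudoexon_max_bp,
            "dp_convention": th.dp_convention.value,
            "nmd_distance_nt": th.nmd_distance_nt,
        },
    }
    logger.info(
        "annotated %d records (%d rows written, %d without transcript)",
        len(parsed.records),
        len(rows),
        n_no_transcript,
    )
    return report


# ---------------------------------------------------------------------------
# benchmark


def _type_set(cell: str) -> frozenset[str]:
    if not cell or cell in (".", "no_impact"):
        return frozenset()
    return frozenset(t for t in cell.split(";") if t and t != "no_impact")


def run_benchmark(predictions_path: str | Path, labels_path: str | Path) -> dict:
    """Score a predictions TSV against a label TSV sharing (variant, gene) keys.

    Sensitivity = predicted-spliceogenic among label-spliceogenic;
    specificity = predicted-negative among label-negative; per-type accuracy
    = fraction of label positives of that type whose prediction includes the
    type.  Exact-size and frame agreement are reported for the rows where
    the label carries them.  Key mismatches are listed, excluded and warned.
    """
    pred = pd.read_csv(predictions_path, sep="\t", dtype=str).fillna(".")
    labels = pd.read_csv(labels_path, sep="\t", dtype=str).fillna(".")
    key = ["variant", "gene"]
    merged = labels.merge(pred, on=key, how="inner", suffixes=("_label", "_pred"))
    missing_in_pred = labels.merge(pred[key], on=key, how="left", indicator=True)
    unmatched = missing_in_pred[missing_in_pred["_merge"] == "left_only"]
    if len(unmatched):
        logger.warning("%d label rows have no prediction; excluded", len(unmatched))

    label_types = merged["aberration_types_label"].map(_type_set)
    pred_types = merged["aberration_types_pred"].map(_type_set)
    label_pos = merged["spliceogenic"].str.lower().isin(["yes", "true", "1"])
    pred_pos = pred_types.map(bool)

    n_pos = int(label_pos.sum())
    n_neg = int((~label_pos).sum())
    tp = int((label_pos & pred_pos).sum())
    tn = int((~label_pos & ~pred_pos).sum())

    per_type: dict[str, dict] = {}
    all_types = sorted({t for s in label_types for t in s})
    for t in all_types:
        idx = merged.index[label_types.map(lambda s: t in s)]
        correct = int(sum(t in pred_types[i] for i in idx))
        per_type[t] = {
            "n": len(idx),
            "accuracy": correct / len(idx) if len(idx) else float("nan"),
        }

    exact_type = int((label_types == pred_types).sum())
    size_cols_ok = all(
        c in merged.columns
        for c in ("inserted_bp_label", "inserted_bp_pred", "deleted_bp_label", "deleted_bp_pred")
    )
    exact_size = None
    if size_cols_ok:
        exact_size = int(
            (
                (merged["inserted_bp_label"] == merged["inserted_bp_pred"])
                & (merged["deleted_bp_label"] == merged["deleted_bp_pred"])
            ).sum()
        )
    frame_ok = None
    if "frame_effect_label" in merged.columns and "frame_effect_pred" in merged.columns:
        frame_ok = int((merged["frame_effect_label"] == merged["frame_effect_pred"]).sum())

    report = {
        "n_compared": len(merged),
        "n_label_only": int(len(unmatched)),
        "n_pred_only": int(len(pred) - len(merged)),
        "n_spliceogenic": n_pos,
        "n_non_spliceogenic": n_neg,
        "true_positives": tp,
        "true_negatives": tn,
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "per_type_accuracy": per_type,
        "exact_type_match": exact_type,
        "exact_size_match": exact_size,
        "frame_match": frame_ok,
    }
    return report


def run_fixtures(seed: int, outdir: str | Path, n_per_type: int = 30) -> dict:
    """Emit the forged corpus as FASTA/GTF/TSV/VCF files plus the label table."""
    from .fixtures import build_corpus, write_corpus_files

    cases = build_corpus(seed, n_per_type)
    paths = write_corpus_files(cases, outdir)
    return {"n_cases": len(cases), "paths": {k: str(v) for k, v in paths.items()}}
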