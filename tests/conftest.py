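import pytest

from splicefx.fixtures import build_corpus
from splicefx.model import SpliceAIRecord, TranscriptModel, Variant


def make_record(t: TranscriptModel, variant_pos: int, sites=None, scores=None,
                ref="A", alt="C") -> SpliceAIRecord:
    """Hand-forge a record with genome-forward dp offsets to the given sites."""
    sites = sites or {}
    scores = scores or {}
    variant = Variant(t.contig, variant_pos, ref, alt)

    def dp(key):
        return sites[key] - variant_pos if key in sites else 0

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


@pytest.fixture(scope="session")
def three_exon_plus():
    """Exons (101,200),(301,464),(701,800) on '+': intron1 100 bp, intron2 236 bp,
    internal exon 164 bp."""
    return TranscriptModel(
        gene_symbol="TOY1",
        transcript_id="NM_900001.1",
        contig="chrT",
        strand="+",
        exons=[(101, 200), (301, 464), (701, 800)],
        cds_start=131,
        cds_end=770,
    )


@pytest.fixture(scope="session")
def five_exon_plus():
    """Five exons; exons 2 and 3 are 90 and 120 bp."""
    return TranscriptModel(
        gene_symbol="TOY5",
        transcript_id="NM_900005.1",
        contig="chrT",
        strand="+",
        exons=[(101, 200), (401, 490), (701, 820), (1001, 1100), (1301, 1400)],
        cds_start=131,
        cds_end=1370,
    )


@pytest.fixture(scope="session")
def acceptance_corpus():
    """The seeded forged corpus used by the acceptance surface (30 per category)."""
    return build_corpus(seed=20230406, n_per_type=30)


@pytest.fixture(scope="session")
def small_corpus():
    return build_corpus(seed=11, n_per_type=3)
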