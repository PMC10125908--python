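# splicefx

Interpret SpliceAI delta scores as concrete splicing aberrations.

SpliceAI reports, for each variant, four delta scores — acceptor gain
(DS_AG), acceptor loss (DS_AL), donor gain (DS_DG), donor loss (DS_DL), each
in [0, 1] — and four delta positions (DP_*) locating the affected splice
site within ±4999 bp of the variant.  Most workflows stop at "max delta
score above threshold ⇒ likely spliceogenic".  `splicefx` goes further: it
combines all four score/position pairs with the exon/CDS structure of a
chosen RefSeq transcript and predicts, for every single-nucleotide variant:

* the **aberration type** — pseudoexonization, partial intron retention,
  partial exon deletion, (multi-)exon skipping, or whole intron retention,
  including legal combinations of these;
* the **exact inserted/deleted size** in bp, computed against the
  transcript's *native* (annotated) splice sites, which is what makes the
  sizes exact for deep-intronic and cryptic-site variants;
* the **reading-frame effect** (Δ mod 3);
* the **altered amino-acid sequence** in a compact bracket notation, with a
  premature-termination-codon position and an NMD/truncated-protein flag
  (50-nt rule).

Indels are deliberately not interpreted: their delta positions have
ambiguous anchor semantics, so such rows are skipped and counted.

## Calling model

With transcript-orientation coordinates and the SpliceAI site anchors
(donor = last exonic base, acceptor = first exonic base):

| evidence | condition (defaults) | call | size |
|---|---|---|---|
| AG + DG in one intron, AG 5′ of DG | both ≥ 0.05, size in [25, 500] | pseudoexonization | DG − AG + 1 |
| DG in intron *i* | ≥ 0.05 | partial intron retention | DG − native donor |
| AG in intron *i* | ≥ 0.05 | partial intron retention | native acceptor − AG |
| AG inside exon *e* | ≥ 0.05 | partial exon deletion | AG − native acceptor |
| DG inside exon *e* | ≥ 0.05 | partial exon deletion | native donor − DG |
| AL + DL at both native sites of exon *e* | both ≥ 0.2 | exon skipping | exon length |
| AL at exon *e₁*, DL at exon *e₂* > *e₁* | both ≥ 0.2 | multi-exon skipping | Σ exon lengths |
| DL + AL flanking one intron | both ≥ 0.2 | whole intron retention | intron length |

Scores below the 0.02 noise floor are inert.  Thresholds are inclusive
(score ≥ threshold fires) and tunable.  Three combinations are never
emitted together (exon skipping + multi-exon skipping, exon skipping +
whole intron retention, partial exon deletion + partial intron retention);
colliding detector outputs are resolved by the higher driving score.  The
altered transcript is then rebuilt, translated, and flagged for NMD when
the new stop lies more than 50 nt upstream of the last exon–exon junction.

## Worked example

`splicefx` ships a deterministic toy-corpus generator, so you can exercise
the whole pipeline without any download:

```sh
splicefx fixtures --seed 7 --outdir demo --n-per-type 1
splicefx annotate --vcf demo/variants.vcf --genes demo/genes.tsv \
    --annotation demo/annotation.gtf --fasta demo/genome.fa \
    --out demo/predictions.tsv
```

Selected columns of `demo/predictions.tsv`:

```text
variant            aberration_types         inserted_bp  deleted_bp  frame_effect  protein_notation
ctg0000:1199 A>G   pseudoexonization        433          0           frameshift    PDR[CYSNQNVLELFDPPHLCAVGVETSLPV*]
ctg0002:579 T>G    partial_intron_retention 59           0           frameshift    GNK[TSSRHKCTTLMNPMCYALYSVYKWGELSPKI*]
ctg0005:921 C>A    exon_skipping            0            100         frameshift    LCL[ISYWHLCP*]
ctg0007:1491 C>G   whole_intron_retention   368          0           frameshift    IFV[SRSSPSHAIELACAGSVQWLLK*]
ctg0008:724 A>G    exon_skipping;partial_intron_retention 45 124     frameshift    SSP[*]
ctg0009:512 G>A    no_impact                0            0           none          .
```

Reading the first row: the forged record pairs an intronic acceptor gain
and donor gain 433 bases apart, so a 433-bp pseudoexon is inserted; 433 mod
3 ≠ 0, so the frame shifts.  The notation shows the last three wild-type
residues (`PDR`), then the novel residues through the new stop (`*`) inside
brackets; the stop falls far upstream of the final junction, so
`nmd_predicted` is `yes` for this row.  `ctg0008` shows a legal combination
call: one SNV causing both exon skipping (124 bp removed) and partial
intron retention (45 bp retained).  A run report (counts, thresholds
applied) is printed to stderr as JSON.

On real data, supply your SpliceAI output VCF, a two-column
gene ⇥ RefSeq-transcript TSV, a GTF/GFF3 or refFlat annotation, and the
matching genome FASTA (build GRCh37 or GRCh38 — whichever your inputs use).
Scoring against curated labels uses `splicefx benchmark --predictions ...
--labels ...`, which reports sensitivity and specificity over spliceogenic
labels plus per-aberration-type accuracy.

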