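# Methods

## Scope and model

`splicefx` is a deterministic interpreter: it consumes SpliceAI delta
scores/positions (it never computes them) and converts them, together with
one RefSeq transcript model per gene, into typed splicing-aberration calls,
exact sizes, a rebuilt transcript, and a protein-level consequence.  Only
single-nucleotide variants are interpreted; for indels the delta positions
do not have a well-defined anchor, so such rows are skipped and counted
rather than guessed at.

Coordinates are 1-based inclusive everywhere (the VCF/GTF convention);
refFlat's 0-based half-open starts are converted at read time.  Splice-site
anchors follow SpliceAI's labelling: donor = last exonic base of the
upstream exon, acceptor = first exonic base of the downstream exon, both in
transcript orientation.  Exon and intron indices count along the direction
of transcription.

## Thresholds and parameters

| parameter | default | meaning |
|---|---|---|
| `noise_floor` | 0.02 | scores below this carry no signal at all |
| `loss_call_threshold` | 0.2 | native-site losses at/above this drive exon skipping and whole intron retention |
| `gain_call_threshold` | 0.05 | cryptic-site gains at/above this drive pseudoexon, partial retention, partial deletion |
| `pseudoexon_min_bp` / `max_bp` | 25 / 500 | allowed size of a gained exon |
| `nmd_distance_nt` | 50 | PTC-to-last-junction distance for the NMD rule |
| `dp_convention` | genome-forward | how delta positions map to genome coordinates |

All thresholds are **inclusive**: a score equal to the threshold fires.
The loss/gain defaults reflect the widely used score bands for
native-site-loss events (0.02–0.2) and cryptic-gain events (0.02–0.05); the
25–500 bp pseudoexon band brackets the 50–250 bp range considered optimal
for efficient splicing, with headroom on both sides.  All are exposed as
CLI flags so users can trade sensitivity against specificity.

Delta-position sign convention: the upstream tooling does not document
whether DP values are counted along the forward genomic strand or along the
transcript strand.  The default is genome-forward (position = variant pos +
dp on either strand); strand-relative is a one-flag change
(`--dp-convention strand-relative`), and the conversion is isolated in a
single function (`resolve_dp`) so nothing else depends on the choice.

## Size arithmetic — native-site anchoring

All partial-retention and partial-deletion sizes are measured between the
cryptic site and the transcript's **annotated** native splice site, never a
predicted native-site position.  Measuring against a predicted site
mislocates the boundary whenever the prediction is a few bases off the
annotation, inflating or deflating the size by that offset; anchoring on
the annotation makes the size exact by construction.  Conventions (all
transcript-orientation, 1-based inclusive):

* pseudoexon: `DG − AG + 1` (both boundary bases included, consistent with
  exon-length arithmetic);
* partial intron retention: `DG − native donor` or `native acceptor − AG`
  (the count of retained intronic bases);
* partial exon deletion: `AG − native acceptor` or `native donor − DG`
  (the count of lost exonic bases); a gain exactly at the native boundary
  is a 0-bp no-op and is suppressed;
* exon skipping / whole intron retention: genomic feature length.

## Decision flow and arbitration

The four signals are localized first (exon/intron/outside + native-site
matching for losses).  The gain pathway runs before the loss pathway:

1. An intronic AG/DG pair (both ≥ gain threshold, acceptor 5′ of donor, same
   intron) is a *pseudoexon candidate* and consumes both gains.  If its size
   is outside [25, 500] bp the result is no call with an explanatory note —
   the pair is **not** re-read as two partial intron retentions, since the
   paired-gain signature is pseudoexon-like evidence, not two independent
   cryptic sites.
2. Unconsumed gains above threshold become partial intron retention
   (intronic locus) or partial exon deletion (exonic locus).  A matching
   native-site loss is attached as supporting evidence but is not required:
   a cryptic site can be used alongside the native one.
3. Losses at native sites (both ≥ loss threshold) combine by geometry:
   same exon → exon skipping; exons e₁ < e₂ → multi-exon skipping; same
   intron → whole intron retention.  Crossed pairs, terminal-exon losses,
   losses at non-native positions, and lone losses yield explanatory notes
   rather than silent no-calls; a lone loss whose partner native site lies
   beyond the ±4999 bp analysis window is noted as window-limited (whole
   intron retention and multi-exon skipping cannot be assessed there).

Three pairs can never co-occur in one output: {exon skipping, multi-exon
skipping}, {exon skipping, whole intron retention}, {partial exon deletion,
partial intron retention}.  The first two are structurally impossible given
one AL and one DL signal; the third can arise (exonic AG + intronic DG) and
is resolved by the higher driving score.  On a tie the loss-driven call
wins; for the all-gain deletion/retention pair the documented tie-break is
supporting-loss evidence first, then partial intron retention (the
intron-side signal keeps the native exon boundary intact, the weaker
claim).  Every arbitration is recorded in the output notes.

When nothing fires the row is reported as `no_impact` with any unresolved
notes, never dropped.

## Transcript reconstruction and protein effect

Calls edit the exon segment list (insert a pseudoexon segment, remove
skipped exons, extend segments into introns, trim at cryptic exonic sites);
the variant's alternate base is substituted into any retained sequence.
The net length change must equal Σinserted − Σdeleted or the edit aborts
with a consistency error.  The coding sequence is re-extracted by locating
the annotated start codon in the edited mRNA; translation uses the standard
code (Biopython), stops at the first stop codon, ignores a trailing
partial codon, and renders ambiguous codons as `X`.

A stop is premature when it is not the annotated stop codon at its mapped
position.  NMD is predicted by the canonical 50-nt rule against the last
exon–exon junction of the *altered* transcript; a PTC escaping NMD is
reported as a truncated protein.  The bracket notation prints ≤3 wild-type
residues, then the novel residues: through the new stop (`*` inside the
brackets) for frameshifts, or to the re-synchronization point (longest
common suffix) followed by three wild-type residues for in-frame events —
so a clean in-frame deletion prints as `XXX[]YYY`.  Edits that remove the
annotated start codon suppress protein prediction with a
`start-codon-disrupted` note, since translation initiation can no longer be
located; this case is intentionally conservative.

## Synthetic fixtures: what they emulate and what they do not

`splicefx.fixtures` builds toy genes (random exon/intron geometry, GT…AG
introns, ATG…stop CDS free of internal in-frame stops, 1-based coordinates
on a private contig) and forges SpliceAI records whose ground truth — types,
sizes, net length change, frame — is fixed by construction at generation
time and never computed by the engine under test.  The corpus covers every
aberration type on both strands, a legal combination (skipping + partial
retention), a window-limited lone loss, boundary sizes, and negatives with
all scores below the noise floor.

Forged scores are placed constants, not model outputs: passing tests show
the *interpretation layer* is exact (geometry, sizes, frame, translation,
arbitration), not that SpliceAI's scores are accurate on real sequence, and
not how the calculator performs on real assay-validated variants — that
requires curated splicing-assay labels and real SpliceAI scores, which the
`benchmark` subcommand consumes when available.  Real-data features the
toys do not emulate: non-canonical splice-site motifs, overlapping genes,
multi-transcript loci (one transcript per gene is a deliberate contract),
alternative conventions in third-party SpliceAI post-processors, and masked
vs raw score variants (scores are taken as given).

Default corpus size is 30 cases per category (330 total); generation and
the full pipeline run in seconds, and the sizes are large enough that any
systematic coordinate error in a detector is caught many times over.

## Numerical and degenerate-input choices

* Tie-breaks and boundary semantics are pinned by dedicated cases: score =
  threshold fires; pseudoexon sizes 25 and 500 call, 24 and 501 do not.
* A gain at a native boundary (0-bp event) is suppressed as a no-op.
* Single-exon transcripts have no splice sites; no junction means NMD is
  never predicted.
* Transcripts without CDS annotation load with protein prediction disabled
  (`non-coding-transcript` note).
* Duplicate genes in the gene table: last row wins, with a warning; genes
  absent from the table or annotation are emitted with an explanatory
  qualifier, never silently dropped.
* The in-memory genome loader keeps whole contigs; FASTA access for real
  genomes goes through pyfaidx lazily, so only fetched windows are read.

## Known limitations

* One transcript per gene per run; no canonical-transcript auto-selection.
* No probabilistic confidence tiering (e.g. treating the 50–250 bp optimal
  pseudoexon band as higher confidence) — sizes inside [25, 500] are
  treated uniformly.
* NMD uses the 50-nt junction rule only; EJC-independent and UTR-mediated
  decay routes are out of scope.
* Branch order inside the decision flow is this package's own
  reconstruction of common practice; other interpreters may order
  gain/loss arbitration differently in rare multi-signal collisions.
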