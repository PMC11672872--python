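# Methods

## Data model and coordinate conventions

All coordinates are 1-based and inclusive, the GTF/GenBank convention.
A transcript is an ordered chain of genomic exon intervals in transcription
order (genomically descending on the minus strand) plus an optional CDS span
in transcript coordinates, counted from 1 at the mRNA 5′ end. The CDS runs
from the first base of the start codon through the **last base of the stop
codon** (RefSeq convention), so the three regions tile the mRNA exactly:

    len_5utr = cds_start − 1
    len_cds  = cds_end − cds_start + 1
    len_3utr = spliced_length − cds_end

Poly-A tails are not part of the annotation and never counted in the 3′UTR.
Non-coding transcripts are retained (full length, exon count) but excluded
from 5′UTR/CDS/3′UTR statistics, which are defined only for coding mRNAs.

CDS codon-divisibility is checked but only *warned* about, not enforced:
annotated CDS lengths in published per-gene tables are occasionally off by a
base from a codon multiple, and the packaged worked-example fixture
faithfully reproduces one such printed value (Mta3 variant 1, CDS 1757 nt).

Three annotation dialects are read: GTF (attributes `transcript_id` /
`gene_id`, optional `gene_name`; a trailing `stop_codon` feature is folded
into the CDS span), GFF3 (`Parent`/`ID` linkage), and a compact tabular
dialect (`transcript_id, gene_symbol, chrom, strand, exon_starts, exon_ends,
cds_start_tx, cds_end_tx`) that round-trips exactly and is what the
generator and fixtures use.

## Volcano filtering and list merging

Expression records carry an isoform-level `seqname`, a gene-level symbol, an
absolute (non-log) fold change and a t-test p-value. The filter keeps
records with FC ≥ 2.0 **and** p ≤ 0.05, boundaries inclusive; both
thresholds are parameters. Fold changes are never log-transformed by the
reader — they are defined as plain ratios. Duplicate seqnames within one
table keep the smallest-p row (logged); the merge of two condition lists is
a stable sort on the gene symbol, case-insensitive because microarray symbol
casing is inconsistent, with ties broken by condition then seqname so the
order is fully deterministic.

## Length-distribution comparisons

Query-vs-reference region lengths are compared with a two-sample *t*-test on
log₁₀ lengths, Welch's unequal-variance form by default. The log scale is
used because mRNA region lengths are strongly right-skewed and close to
log-normal (the reference 3′UTR distribution is explicitly bimodal on the
log scale); Welch is the default because query lists are small relative to
the reference exome and need not share its variance. Both choices are
exposed (`--test {welch,student}`, `--scale {log10,linear}`). The
significance level α defaults to 0.05; the direction is *longer*/*shorter*
only when p ≤ α, else *none*. Identical samples short-circuit to exactly
t = 0, p = 1.

Zero-length UTRs (transcripts with no annotated UTR) cannot enter a
log-scale test; they are excluded and reported as a separate count. Each
comparison requires at least three positive lengths per side.

Density curves for plotting use a Gaussian KDE on log₁₀ lengths with
Silverman's bandwidth rule, evaluated on a shared 256-point grid spanning
both samples with 10 % padding; each curve integrates to 1 within 0.01
(trapezoid rule, asserted in tests). The reference exome is **all** coding
transcripts of the loaded annotation, not only expressed ones.

## Exon-count spectra

A gene's exon count is the mean number of exons across its annotated
isoforms (hence decimal values for genes with alternatively spliced
variants), rounded half-up for binning into categories 1..9 and "10+".
Query bin counts are tested against reference bin proportions scaled to the
query total with a χ² goodness-of-fit statistic, Σ(O−E)²/E. Bins with zero
expected count are merged into the adjacent bin (upward; the last bin folds
downward) and the merge is logged, so expected counts are always positive.

## Isoform switching

For two filtered condition lists, every gene with records in both is
compared through its seqname sets: isoforms only in the later condition are
*de novo*, only in the earlier one *silenced*; the event class is
`no_switch`, `de_novo_isoform`, `isoform_loss` or `mixed`. Events are
emitted for non-switching genes too, so shared-gene counts remain
recoverable from one output. Switch tables emit every old × new isoform
pair (the lossless choice when a gene has several isoforms on both sides)
with S/L/= codes per region; "=" requires exact nucleotide equality — a
published table treats a 4-nt difference as S, so no tolerance is
defensible.

## Mechanism classification

Junctions are genomic (donor, acceptor) pairs — donor the last base of the
upstream exon, acceptor the first base of the downstream exon, strand-aware.
The cascade, first match wins:

1. **identical** — equal exon chains and equal CDS bounds.
2. Same junction chain: a different 3′-terminal end with a shared stop codon
   is **alternative polyadenylation**; a different genomic start codon with
   a shared stop is an **alternative start codon**; anything else is
   complex.
3. **cassette exon inclusion/skipping** — exactly one *internal* exon of one
   isoform absent from the other, and removing it merges its flanking
   junctions into a junction of the partner. Terminal exons are never
   cassettes.
4. **mutually exclusive terminal exons** — both 3′-terminal exons disjoint
   from every exon of the partner isoform, upstream chains identical.
5. **alternative 5′ donor / 3′ acceptor** — differing junctions paired by
   their shared endpoint, the affected partner exons overlapping
   genomically; an unpaired junction whose endpoint falls strictly *inside*
   a partner exon is also a donor/acceptor call and carries the **cryptic**
   tag (a latent site activated within exonic sequence). Multiple
   conflicting calls collapse to **complex**.

The terminal-exon check runs *before* the site-shift analysis deliberately:
a swapped terminal exon downstream of a shared exon necessarily shares its
donor, so an unguarded acceptor-shift rule would shadow the
mutually-exclusive class entirely. The overlap guard on site shifts is what
separates a shifted acceptor (same exon, moved boundary) from a wholly
different exon. The cascade order (polyadenylation before cassette before
site shifts) resolves multi-class ambiguity deterministically; `complex` is
the honest fallback rather than a forced single label.

Single-codon skipping at an exon–exon junction in the 5′UTR is classified as
an alternative 3′ acceptor; no special micro-exon class exists. A gene pair
whose tables describe "alternative exons in CDS and 3′UTR" via mutually
exclusive terminal structures is encoded and classified as mutually
exclusive terminal exons.

### Splice-signal scoring

Donor windows cover the last 3 exonic + first 6 intronic bases (9-mer,
consensus `MAG|GURAGU`); acceptor windows the last 14 intronic + 1 exonic
base (15-mer, consensus `YYYYYYYYYY·N·YAG|G`). Window sizes follow standard
consensus presentations and are config-exposed since no single convention is
universal. The consensus score is the fraction of positions compatible with
the IUPAC code (U ≡ T; N matches everything), so it lies in [0, 1] and a
canonical site scores 1.0.

## Worked-example fixture

The nine switching genes are shipped as a static tabular fixture
(`isoform_fixture_synthetic.tsv`). Coordinates are constructed — the true
genomic coordinates are not recoverable from the published per-gene tables —
but every derived quantity the analysis consumes is exact: region lengths
(Mta3 3′UTR 93 → 820 nt, CDS 1542 → 1757 nt), all S/L/= codes, mechanism
classes and cryptic tags. The fixture loader embeds the genes in condition
lists with single-isoform distractor genes (107 for the progression pair,
150 for the treatment pair) so the shared-gene totals are 114 and 153 and
the switch counts (7 and 3) emerge from detection, not construction.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis assumes.

**Lengths.** 3′UTRs follow a two-component log-normal mixture on the log₁₀
scale — means 2.0 and 3.0 (modes ≈ 100 bp and 1000 bp), SDs 0.25/0.30,
long-component weight 0.5 — matching the bimodal reference distribution.
5′UTRs are log-normal peaking at 100 bp (log₁₀ mean 2.0, SD 0.25); CDS
lengths log-normal with log₁₀ mean 3.1, SD 0.25, floor 150 nt, rounded to a
codon multiple. Exon counts are categorical over 1..15 with a broad peak at
4–6; per-gene isoform counts are 1–3 with probabilities 0.6/0.25/0.15; 5 %
of genes are non-coding. Intron lengths are uniform on [60, 2000] nt —
irrelevant to mRNA-level statistics but large enough for splice-signal
windows. Where the study conditions stated no value, these were chosen once
as field-plausible and are exposed as config, not revisited.

**Structure.** Each gene sits on its own contig, built on the plus strand
and mirrored to the minus strand with probability ½ (a pure coordinate
flip, preserving every transcript-level quantity — asserted by the strand-
symmetry tests). Planted switch pairs are realised by structural editors,
one per mechanism class (acceptor shift inside the 5′UTR, cryptic donor in
the terminal exon's CDS tail spliced to a novel downstream exon,
frame-preserving cassette insertion, downstream start codon, terminal-exon
swap, terminal-exon extension for polyadenylation); the default mechanism
mix gives alternative polyadenylation zero weight — the planted events are
splicing-driven, and the class stays available as an explicit knob.

**Sequence.** Contig sequences are uniform random bases with every annotated
feature physically planted: ATG at each CDS start, TAA at each CDS end, and
canonical GT/AG dinucleotides at every intron, including activated cryptic
junctions (ground truth lists them). Constraints from sibling isoforms of
one gene are reconciled; an *extra* (unplanted) isoform whose constraints
clash is discarded, a planted pair is rebuilt until conflict-free. The
generator does not scrub internal in-frame stop codons from CDSs and does
not model probe-level intensities, normalisation or co-expression — passing
tests therefore validate coordinate arithmetic, set logic and statistical
behaviour, not microarray chemistry.

**Condition lists.** Lists have exactly the configured sizes (defaults
489/1285/300/690 for C10/C24/T10/T24) with configured shared-gene overlaps
(114 for C10/C24, 153 for T10/T24) and planted switch counts (7 and 3,
realised as a de novo isoform appearing in the later condition). Fold
changes and p-values are drawn inside the volcano thresholds, so filtering
is the identity on generator output. Condition-specific 3′UTR dynamics are
realised by weighting each condition's gene draw by mixture component
(Gumbel top-k sampling without replacement): the long-component weight is
multiplied by 0.6 for C10 and 1.6 for C24 (treatment conditions 1.0), which
reproduces the qualitative progression picture — C10 *shorter*, C24
*longer*, treatment arm not significant against the exome. No effect size
was stated for the lengthening; the multipliers were chosen once to make
the planted effect clearly detectable at the configured list sizes. Each
condition pair samples the gene pool independently (cross-pair overlap is
unconstrained), so one pair's bias cannot deplete another's.

**Determinism.** All draws flow from `numpy` Generators seeded by the
config; sequence synthesis uses a decoupled stream so that skipping it does
not change the models. A fixed seed reproduces byte-identical
FASTA/GTF/TSV outputs.

## Pipeline and reproducibility

The pipeline runs filter → lengths → distribution stats → exon spectra →
switch detection (both condition pairs) → mechanism classification →
report. Every output TSV carries the config hash (SHA-256 over the
parameters, excluding the output directory) and seed as comment headers;
stage counts are logged and written to `summary.tsv`; a stage failure
aborts with the stage name while preserving partial outputs. Empty input
tables produce a clean run with empty outputs and explicit zero counts.

## Problem sizes and test design

The test suite validates on reduced problem sizes chosen to keep the
statistical checks well-powered: a 220-gene simulation for structural and
pipeline tests, 1000 replicates for type-I-error calibration of the length
test (observed rate within ±2 points of the nominal 5 %), 100 seeds at
n = 500 for the power of the planted 3′UTR lengthening (≥ 95 detections
required), 200 standalone pairs for mechanism-recovery (≥ 95 % exact class
required), and 100 seeds at 300 genes for the exon-spectrum excess test
(≥ 90 significant required). `scripts/acceptance.py` recomputes the
worked-example quantities at full fixture size and the simulation
quantities at the full default list sizes.

## Known limitations

* Mechanism classification is structural: it compares annotated exon
  chains, so it cannot distinguish mechanisms that produce identical
  structures (e.g. alternative promoters that mimic a TSS shift fall to
  `complex` or `alternative_start_codon` depending on the CDS).
* The switch model is presence/absence over filtered lists; no
  isoform-usage fractions are computed, because probe-level quantitation is
  out of scope.
* The dual-route acceptor/donor consensus is a fixed IUPAC window score,
  not a trained position-weight matrix or maximum-entropy model.
* The generator's genes are structurally independent (one gene per contig,
  no overlapping loci, no trans-splicing or fusions), and splice sites are
  canonical GT/AG by construction.
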