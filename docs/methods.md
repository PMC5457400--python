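# Methods

This note documents the models, conventions and numerical choices behind
`splicescape`, and what the synthetic benchmark does and does not show.

## Coordinates, strands, sequences

All internal intervals are 0-based half-open on genomic coordinates;
GTF/GFF3 I/O converts from/to 1-based inclusive at the file boundary.
Exons are stored in genomic order and reordered on demand for
transcription order.  Every sequence-facing operation receives 5′→3′
transcript-oriented sequence: minus-strand spliced transcripts,
pre-mRNAs, intron ends and splice-signal windows are
reverse-complemented before use, so a genomic `CT..AC` minus-strand
intron reports its dinucleotides as `GT..AG`.

## AS event classification

The hypothetical pre-mRNA of a locus is the interval union of all
isoform exons; its complement inside the locus span is intronic.  Events
come from pairwise isoform comparison:

- *intron retention* — an exon of one isoform fully covers an intron of
  the other; the event interval is the intron.
- *alternative donor / acceptor* — two overlapping introns share one
  boundary and differ at the other, **and** the exons flanking the
  differing boundary overlap.  The flanking-exon condition keeps a
  skipped or swapped cassette exon from also registering as a shifted
  splice site.  Naming is strand-aware (donor = intron 5′ end).
- *exon skipping* — an internal exon of one isoform lies wholly inside
  an intron of the other.
- *mutually exclusive exons* — a skipped exon of each isoform, disjoint,
  with no exon of either isoform between them (same cassette slot);
  matched pairs are removed from the exon-skipping lists.
- *alternative TSS / TTS* — the strand-aware transcription start/end
  coordinates differ; the interval spans the two alternatives.

Events are deduplicated by (type, interval) across all pairs.  An
independent brute-force comparator (position-set logic) reproduces the
classifier exactly on 200 random 2–4-isoform structures, and the planted
event registry of the synthetic benchmark is recovered exactly.

## Junction catalogue and U2/U12 typing

A junction is *alternative* iff an isoform whose span covers it does not
splice it identically, or it borders an AS event interval.  Junctions
adjacent to first exons or flanking retained introns can be excluded
from typing (`junctions_for_typing`), since their signal context is
atypical.

Typing scores windows against position probability matrices (PPMs) as
log-odds in bits against a uniform background; ambiguous bases
contribute 0.  Window geometry: donor −3..+10 around the 5′ splice site,
acceptor −14..+3, and the U12 branch box scanned over −40..−10 of the
acceptor with the maximum taken over offsets.  U2 score = donor +
acceptor; U12 score = donor + best branch.  Ties go to U2 (the major
spliceosome dominates overwhelmingly in plants); both scores below a
floor (default 0 bits) yield `unclassified`.

The default PPMs are built from plant splice-site consensus: U2 GT..AG
donor `GTAAGT…`, polypyrimidine acceptor `…YYYYNCAG`, U12 AT-AC donor
`ATATCCTT` and branch box `TTCCTTAAC`, with probability floor ε = 0.01
and uniform (uninformative) exon-side positions so that coding sequence
abutting a splice site cannot perturb typing.  The matrices ship as code
and round-trip through YAML, so a user can substitute empirical ones.

## Isoform usage and switch calling

IF is computed on condition-mean FPKM; a gene with zero FPKM in a
condition has undefined (NaN) fractions, never zero.  dIF is signed,
reference → contrast, in percentage points (the 20-point threshold
implies a percent scale).  The switch score is √JSD with base-2
logarithms (scipy's `jensenshannon` already returns the square root);
the unit test freezes a hand-derived oracle value
√(H(¾,¼) − ½H(½,½)) ≈ 0.55792.

Significance is a label-permutation test on √JSD between condition-mean
abundance vectors: exhaustive over all C(n₁+n₂, n₁) assignments when
that count is ≤ 2000, Monte-Carlo otherwise, with the observed labelling
included so p > 0.  Because √JSD is symmetric, the observed labelling
and its mirror always tie, so the attainable minimum is 2/C(2r, r) with
r replicates per condition — at least 4 replicates are needed before p
can fall below 0.05.  The synthetic expression generator therefore
defaults to 5 replicates per condition (min p = 2/252 ≈ 0.0079), giving
the test usable resolution under Benjamini–Hochberg correction.  When
within-condition variance is exactly zero (noise-free data) or
replicates are absent, the permutation test is degenerate and the
threshold-only mode (`significance_mode="threshold_only"`) applies the
|dIF| rule alone, with the result marked accordingly.

DE calling clamps FPKM at the 0.2 floor before the log-ratio (the floor
is stated; zero-handling is our choice) and excludes genes below the
floor in both conditions.

## Proteogenomics

ORF prediction is a longest-ORF scan over the three sense frames with a
required ATG and a 100-codon minimum (homology rescue is out of scope);
stop-less ORFs reaching the transcript end are flagged partial.  The
5′-UTR length is the ORF start offset on the spliced transcript.

Trypsin cuts C-terminal of K/R except before P; peptides with up to one
missed cleavage are concatenations of adjacent fragments.  Peptide
occurrence is exact membership in an ORF's digest — not substring
matching against the protein — because an observed tryptic peptide must
be producible by digestion.  I and L collapse for uniqueness by default
(indistinguishable by mass); length bounds 7–50 residues approximate the
MS-observable range.  An isoform-specific peptide occurs in exactly one
isoform ORF of exactly one gene; a gene is AS-confirmed when observed
ISPs cover ≥2 isoforms.

## Detectability resampling

The sampling pool of a gene concatenates each isoform's digest as a
multiset (a peptide shared by k isoforms appears k times — equal molar
abundance semantics; a distinct-peptide frame is available by flag).
Per replicate and gene, as many peptides as the experiment observed are
drawn without replacement (the whole pool when smaller), and the gene
counts as AS-distinguishable when the draw holds ISPs from ≥2 isoforms
(a ≥1-ISP tally is reported alongside).  Each gene owns an RNG
substream derived from `SeedSequence([seed, crc32(gene_id)])`, so
results are independent of gene order and bit-reproducible from the
seed.  On a two-isoform toy with disjoint 5-peptide digests and draws of
2, the Monte-Carlo rate converges to the exact hypergeometric value 5/9.

## lncRNA–RNA complementarity

Antiparallel hybridisation is modelled by reversing (not complementing)
the lncRNA and running exhaustive Smith–Waterman/Gotoh local alignment
under the pairing matrix (G:C +4, A:U +2, G:U wobble +1, else −6) with
affine gap cost 20 + 8k.  Reversal-plus-pairing is physically equivalent
to reverse-complement-plus-identity; reported intervals stay in each
molecule's native 5′→3′ orientation, and a parallel-orientation flag
exists for comparison.  The DP is exhaustive rather than seeded — at
desk scale this removes heuristic seeding as a correctness variable —
and is row-vectorised (the within-row gap chain becomes a running-max
scan), with full matrices kept for traceback.  Multiple sites per pair
come from iterative masking of each optimal alignment until the score
drops below the threshold.  The score threshold (default 100, the score
of a perfect 25-bp G:C duplex) replaces an E-value model, and the
minimum site length is 25 nt.  An independently written per-cell Gotoh
oracle matches the vectorised scores on random pairs.

Site context: a site is junction-spanning when it strictly covers a
junction boundary from the catalogue (both boundaries of every junction
count, so retained-intron boundaries inside exon-union blocks are
represented); otherwise exonic/intronic by the union blocks.  Enrichment
of alternative junctions among interacted junctions is a two-sided
Fisher exact test with Haldane-corrected odds ratios.  Pair expression
correlation uses Spearman ρ with an exact permutation p for ≤8 samples
(with a warning when n! cannot reach the significance level, e.g.
p ≥ 1/6 at n = 3).  Site sharing between reference and alternative
isoform groups merges genomically-projected overlapping sites per
(lncRNA, gene) into clusters and reports shared/union.

## Synthetic benchmark: what it emulates, and what not

The generator plants, per 40 genes: 8 intron retentions, 5 alternative
donors, 5 acceptors, 6 skipped exons, 2 mutually exclusive pairs, 3
alternative TSS and 2 TTS (retention dominant, as in moss), 2 minor-
spliceosome loci, and genes of 5–6 exons with in-frame (multiple-of-3)
exon lengths, ~0.08 Mb of genome.  Variant splice sites are placed
*inside* the reference intron and consensus bases are written only on
intron sides, so planted reference ORFs (ATG-scrubbed 5′ UTRs, stop-free
codon runs) survive untouched and are recovered exactly by the
predictor.  Expression uses exact condition means (Dirichlet fractions;
planted switches swap the two leading isoform fractions; DE genes shift
totals by ±3 log₂ units) with multiplicative lognormal noise (default
CV 0.1, 5 replicates, three cell-type-like conditions).  MS spectra are
multinomial over peptides with weights ∝ parent-isoform abundance ×
detectability; the dominant-isoform mode (only the most abundant isoform
translated) and the ISP-detectability knob both reproduce the
qualitative transcriptome ≫ proteome gap that the resampling experiment
quantifies — at the 60-gene scale used for that experiment the
equal-expression expectation exceeds the observed AS-confirmed count
(0–1) by well over an order of magnitude.  lncRNAs are intergenic
(carrying one planted antiparallel-complementary 45-nt window, centred
on a retained-intron boundary, with a configurable wobble fraction) or
cis-NAT (antisense copies of a host-gene window, hence perfectly
complementary); co-regulated lncRNAs track their target gene's
per-sample total affinely.

Deliberately *not* emulated: read-level sequencing noise and mapping
ambiguity, isoform-quantification uncertainty (FPKM is taken as given),
spectrum-level MS physics (flyability, charge states, FDR of
identifications), NMD, RNA editing, and hybridisation thermodynamics.
Passing tests therefore certify the computations and their contracts on
idealised inputs, not performance on real libraries.

## Problem sizes and defaults

Default study: 40 genes (~31 multi-isoform), 8 lncRNAs, 15 expression
samples, 4000 spectra; the full pipeline runs in ~20 s and the whole
test suite in about a minute on one CPU.  The detectability experiment
in the acceptance checks uses 60 genes and 6000 spectra so the
expectation estimate is stable across seeds.  All stages are pure
functions of (inputs, config, seed); two runs with the same seed produce
byte-identical tables (the run manifest, which records wall-clock
timings, is the one exception).

## Known limitations

- The permutation DAS test is conservative at small replicate counts by
  construction (discrete p floor); Cuffdiff-style asymptotics are
  intentionally not reproduced.
- Longest-ORF prediction misses non-ATG starts and homology-rescued
  short ORFs; ISP counts depend on the I/L and length-bound conventions.
- The duplex aligner's iterative masking returns greedily non-overlapping
  local optima; a suboptimal-alignment enumeration could differ near
  ties.
- cis-NAT classification uses locus spans, not exon-resolved overlap.
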