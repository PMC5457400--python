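# splicescape

Does alternative splicing (AS) detected in a transcriptome actually reach
the proteome?  `splicescape` is a desk-scale pipeline for asking that
question in plant (bryophyte-style) systems.  It classifies AS events per
locus, types splice junctions as major (U2) or minor (U12) spliceosome
substrates, calls differential isoform usage between conditions, digests
predicted ORFs in silico to find isoform-specific peptides (ISPs),
estimates by resampling how many AS loci *should* be distinguishable in a
given mass-spectrometry experiment if all isoforms were translated
equally, and maps antiparallel lncRNA–(pre-)mRNA complementarity sites
with splice-junction-context enrichment.  A synthetic-data generator with
a planted ground-truth registry makes every stage testable end to end
without any external download.

## The core computations

**AS events.**  For each locus a hypothetical pre-mRNA (the interval
union of all isoform exons) is built and isoforms are compared pairwise:
intron retention, alternative donor (5′) / acceptor (3′) sites, exon
skipping, mutually exclusive exons, and alternative TSS/TTS, all
strand-aware, deduplicated by (type, interval).

**U2/U12 junction typing.**  A junction's donor, acceptor and
branch-point windows are scored against position probability matrices as
log-odds in bits, `score = Σᵢ log₂(pᵢ(bᵢ)/0.25)`.  The subtype is the
argmax of (U2 donor + acceptor) vs (U12 donor + best branch window in
−40..−10 of the acceptor); ties resolve to U2.

**Isoform switches.**  The isoform fraction IFₜ,c = 100·FPKMₜ,c / Σ FPKM
over the gene; dIF = IF(contrast) − IF(reference) in percentage points;
the per-gene switch score is √JSD, the square root of the Jensen–Shannon
divergence (log₂) between the gene's isoform-fraction vectors, in [0, 1].
A gene is differentially alternatively spliced (DAS) when some isoform
has |dIF| > 20 and a label-permutation test on √JSD is significant after
Benjamini–Hochberg correction.  Differential expression uses the
fold-change rule |log₂(FPKM_y/FPKM_x)| > 2 with an FPKM floor of 0.2.

**Proteome evidence.**  ORFs are predicted by a longest-ATG-ORF scan
(≥100 codons), digested with trypsin (cut after K/R, not before P, one
missed cleavage), and each peptide is classified multi-gene,
gene-unique-shared, or isoform-specific (I/L collapsed).  A locus is
AS-confirmed at the proteome level when observed ISPs cover ≥2 isoforms.
The detectability simulation pools each gene's per-isoform digests
(equal-molar multiset), redraws as many peptides per gene as the real
experiment observed, and counts AS-distinguishable loci across 100
replicates.

**lncRNA interactome.**  Candidate lncRNAs (>200 nt, FPKM ≥ 0.5, no ORF
≥ 100 codons, unannotated class codes) are aligned — reversed, under the
pairing matrix G:C = +4, A:U = +2, G:U = +1, else −6, gap cost 20 + 8k —
against pre-mRNAs by exhaustive affine-gap local DP with iterative
masking.  Sites are classed exonic / intronic / junction-spanning,
enrichment of alternative junctions among interacted junctions is tested
with Fisher's exact test, and per-pair expression correlation uses
Spearman's ρ with an exact permutation p.

## Worked example

Generate a 14-gene synthetic study and run the full pipeline:

```
$ splicescape generate --seed 1 --out demo --n-genes 14
wrote 7 files to demo
$ splicescape run --input-dir demo --out demo_run --seed 1
pipeline complete: demo_run
```

`demo_run/das_genes.tsv` holds the per-gene switch calls; the called
rows are exactly the generator's planted switches (dIF of 30/50/70 in
alternation, lognormal noise CV 0.1, 5 replicates per condition):

```
         sqrt_jsd  max_abs_dif  pvalue  qvalue   das
g001       0.2378      26.4054  0.0079  0.0119  True
g002       0.4657      50.8645  0.0079  0.0119  True
g003       0.6303      70.5637  0.0079  0.0119  True
...
```

`pvalue = 0.0079` is the exhaustive-permutation floor 2/C(10,5): the
observed labelling and its mirror out of all 252 assignments.

`demo_run/detectability_summary.json` contrasts proteome-level
expectation and observation.  The demo's MS data were generated in
dominant-isoform mode (only the most abundant isoform is translated), so
no AS locus is confirmed, while equal-expression resampling expects ~4.5
of these 14 loci to be distinguishable — the transcriptome shows far
more splicing than the proteome can echo:

```
{"expected_mean": 4.52, "expected_sd": 0.659, "n_reps": 100,
 "observed": 0, "verdict": "ratio undefined (observed count is 0)"}
```

`demo_run/lnc_summary.json` reports 8 retained lncRNAs (2 cis-NAT), 8
pre-mRNA interaction sites, the alternative-junction enrichment table
and a 33% overlap between sites found on reference vs alternative
isoforms.  At the default 40-gene scale the enrichment is significant
(odds ratio 9.3, p = 0.0048, seed 1).

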