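# Methods

## Scope and model of the data

The package analyses post-alignment artifacts of a two-condition hNPC
experiment (control vs DNMT1 knockout): per-cytosine bisulfite calls,
stranded paired-end RNA alignments, ChIP alignments, and CRISPR amplicon
alignments. Read alignment itself is out of scope; alignment files (SAM)
carry the uniqueness evidence (NH tag, MAPQ) the filters act on.
Coordinates are 0-based half-open everywhere in memory; GTF input
(1-based inclusive) is converted at the parser boundary, and coverage
files are read in a bedGraph-style 0-based dialect.

## Methylation summaries

A CpG (or CH) site contributes its per-site ratio n_meth/(n_meth+n_unmeth)
only when coverage ≥ 3 (the `min_coverage` default, applied uniformly to
region, tile and global summaries; overridable). Two conventions are
always available:

* **site-mean** — the mean of per-site ratios; the default for regions and
  1-kb tiles, because the per-element and per-tile views are defined as
  means of site-level mCpG/CpG.
* **read-weighted** — Σ n_meth / Σ coverage; the default for genome-wide
  levels, where deeper sites carry proportionally more evidence.

A summary with zero qualifying sites is flagged undefined rather than
given a value. CpG calls on the two strands are treated as distinct sites
(no destranding), matching the upstream extraction workflow. The two
conventions agree to ~1e-3 on the simulated Beta methylomes; both are
reported by `global_methylation` so the choice is explicit.

## Locus-level TE expression

One count unit is a *fragment* (a properly paired template), not a read:
this avoids double-counting mates and makes the uniqueness decision
template-level (both mates must be primary with NH=1, or MAPQ ≥ 10 when
NH is absent). Strand under the dUTP protocol is the strand of mate 2.
A fragment is assigned to the single TE locus with the largest base
overlap against the union of its aligned blocks, ties to the
lower-coordinate element; a featureCounts-like `discard` mode for
ambiguous overlaps is one flag away. TEs overlapping any annotated exon
are removed before counting, so spliced mRNA fragments cannot inflate TE
counts. Elements with fewer than five fragments summed over all samples
are dropped. TE matrices are normalized sample-wise by total genome-mapped
fragments (library scaling); gene matrices use the median-of-ratios method
(median taken on the log scale, verified against an independent
implementation).

### Differential test

Per feature, group means are total-count estimates μ̂_g = (ΣK + 0.5)/Σs on
the normalized scale; the half-fragment continuity total keeps an all-zero
group finite, so "silent in control, expressed in KO" yields a large
positive log2 fold change instead of infinity. The NB dispersion α is
estimated by method of moments from within-group variances, then shrunk on
the moment scale toward a robustly fitted trend α(μ) = a₀ + a₁/μ with
prior weight d₀ = 10 pseudo-degrees of freedom against d = n₁+n₂−2
residual degrees of freedom. The Wald statistic
log(μ̂_B/μ̂_A) / √(1/(μ̂_A S_A) + αΣs²_A/S²_A + …) is referred to a t
distribution with d + d₀ degrees of freedom (a moderated-t reference, in
the limma spirit), acknowledging that α is estimated. BH adjustment
excludes features with undefined p (no counts anywhere). On 10⁴ simulated
null features at moderate depth (NB mean 30, α = 0.1, 3 vs 3) the
empirical type-I error at nominal 0.05 is ≈ 0.04–0.06; at very low counts
the test is deliberately conservative (discreteness dominates), which is
the desired behaviour for weakly expressed repeats.

### Rank-sum tests

Sense-vs-antisense expression and the near-gene shift use a two-sided
Wilcoxon rank-sum test: exact by enumeration over all label assignments of
the observed midranks when the combined sample is ≤ 20 (so ties are exact,
fully separated triples give p = 0.1, and identical singletons give
p = 1), and the continuity/tie-corrected normal approximation otherwise.

## Fusion reads and promoter candidates

A promoter candidate is an (element, transcript) pair whose annotated TSS
base falls inside an L1 or LTR12C interval; orientation of the element
relative to the gene is recorded (antisense is the expected geometry for
L1 ORF0-style promoters). A fusion read is a fragment with ≥ 1 bp aligned
overlap to a TE **and** to an exon of a protein-coding transcript, with
fragment strand equal to the gene strand; the TE-side orientation is
unrestricted. Exon-level overlap is the default on the gene side (a
whole-transcript-span mode exists) because intronic overlap alone would
admit ordinary pre-mRNA fragments. Evidence is `split-read` when one
mate's spliced blocks provide both overlaps and `spanning-pair` when the
mates provide them separately; both count by default, since 2×150 bp
pairs frequently bridge the junction across mates. The gene × sample
fusion matrix keeps only genes with a TSS-overlap candidate and is
library-scaling normalized.

## Proximity analysis

Distance is the minimal gap between the gene body (widest transcript
span; a TSS-anchored mode exists) and an upregulated element, strand-blind
and 0 when overlapping; genes within 50 kb form the near set. The
background is all other genes passing the expression filter. The shift
statistic is the difference of mean log2 fold changes with the rank-sum p
above.

## CRISPR indel diversity

The window is the expected cut position ± 10 bp. A read enters the
denominator only when its alignment spans the entire flanked window
(guarding against end-truncation artifacts); substitution-only reads
count as unmodified. CIGAR I/D operations intersecting the window are
extracted; two or more on one read collapse to a single complex event
keyed by the full local alternate haplotype. Insertions and deletions are
left-aligned through repeat context (the canonical position is the
smallest equivalent one), so every equivalent placement of the same
physical edit maps to one unique variant. Frequencies are relative to the
informative-read denominator — unique-event frequencies plus the
unmodified fraction sum to one — and frame class is net length mod 3,
with complex events classified by their summed net length.

## ChIP tracks and metaprofiles

Coverage tracks are full-span read coverage in fixed bins (default 10 bp)
after excluding secondary/supplementary records and MAPQ < 10, scaled to
counts per million filtered reads; a track therefore sums to
10⁶ × span/bin_bp up to edge effects. Tracks combine as element-wise
replicate means or as log2((IP+ε)/(input+ε)) with pseudocount ε = 1 CPM
unit. Heatmap rows are elements with the body rescaled to 60 bins by
proportional-window averaging (exact via cumulative sums), 1-kb flanks in
10 fixed bins each, and minus-strand rows reversed so the 5′ end is
always the left edge; elements shorter than the bin target are
interpolated and flagged. The scalar geometry statistic,
`five_prime_contrast`, is the mean over the 5′ quarter of the body minus
the mean over the rest — near zero for flat profiles and strongly
positive for promoter-proximal enrichment. It is preferred over
max-minus-median, which is dominated by single-bin noise at desk-scale
depth.

## The synthetic dataset

The generator emits a 2 Mb, two-chromosome genome. Chromosome 1 carries
the L1 subfamily series (L1HS, L1PA2, L1PA3 young/hominoid; L1PA7, L1M5
old) as consensus-derived copies mutated at a rate tracking age (L1HS
divergence mean 1.37%), a fraction full-length (~6.1 kb) and intact, the
rest 5′-truncated; chromosome 2 carries AluY, HERVK, LTR12C and SVA_D
stand-ins plus most genes. Study conditions are the generator defaults:

* methylomes: per-CpG probability ~ Beta(mean·c, (1−mean)·c), c = 8, mean
  0.79 (control) / 0.079 (KO); CH level 0.004 in both; coverage
  ~ Poisson(10); 10⁴ CpG and 4×10³ CH sites.
* RNA: 3 replicates per condition, NB counts (α = 0.05) per element,
  hominoid L1 copies boosted ×2⁴ in the KO, sense orientation only; 25%
  of hominoid-L1 fragments tagged multi-mapping (NH = 2) to exercise the
  uniqueness filter; non-activated TEs mostly below the five-read filter,
  reflecting that old TEs are transcriptionally silent. Gene transcription
  (NB mean 200/replicate with per-gene log-normal variation) carries the
  bulk of the library, as in poly-A selected mRNA-seq, so that sample-wise
  library scaling measures sequencing depth rather than TE activation.
  Three genes are designed with a full-length antisense L1 containing
  their TSS; in the KO each receives spliced fusion fragments initiating
  inside the L1 and joining exon 2, sense to the gene. Genes within 50 kb
  of an activated element gain log2FC +1.5 in the KO.
* ChIP: uniform background reads plus, in KO IP samples, extra reads over
  the 5′ 900 bp of each activated element ≥ 2 kb; 2 replicates per mark,
  one input per condition; 2% of reads carry MAPQ 5 to exercise the
  filter.
* amplicon: 1.4 kb reference, cut at 700, editing rate 0.935, 12 unique
  canonical indels (geometric deletion sizes, 25% insertions) with
  geometric-decay frequencies so every planted variant is observed at
  n = 5,000 reads.

All randomness derives from the single config seed through fixed
per-stage streams, so outputs are byte-reproducible and independent of
call order. Alignments are emitted directly as SAM records (with NH/MAPQ
tags) rather than via read-level simulation plus an aligner, since
alignment is out of scope.

What the simulation does **not** emulate: sequencing error, mappability
structure of real repeats (multi-mapping is tagged, not caused by
homology), bisulfite conversion failure, bimodal real methylomes (the
Beta is unimodal), fragment-length variation, and polymorphic
(non-reference) L1 copies. Passing tests therefore demonstrate the
correctness of the analysis logic under the stated generative model, not
performance on real libraries.

## Problem sizes and numerical choices

The default dataset (2 Mb genome, ~120 TE copies, 30 genes, ~7,000
fragments per RNA sample, 4×10⁴ reads per ChIP sample, 5,000 amplicon
reads) runs the full pipeline in well under a minute; size knobs on the
config scale everything up. Tolerances used in validation mirror the
sampling bounds at these sizes: global methylation within ±0.01, CH
within ±0.002, indel frequencies within ±0.03 at n = 2,000, editing rate
within ±1.5 percentage points at n = 5,000. Degenerate inputs are flagged
rather than silently valued: zero qualifying CpG sites, empty rank-sum
groups, zero informative amplicon reads, and median-ratio normalization
without an all-nonzero feature all raise or mark undefined. Tie-breaks
are deterministic everywhere (lower coordinate, then identifier), making
every output invariant to input record order.

## Known limitations

The NB test is calibrated, not a bit-exact clone of any existing tool;
with many strong true positives and a calibrated null, BH at finite
feature counts leaves each null feature a small chance of crossing the
adaptive threshold, so "zero false positives" on the activation scenario
is a property of the default conditions and seed, not a guarantee of the
procedure. ORF intactness scanning is a coarse helper (stop-free frames
of configurable minimum length); curated flags are the intended input.
Subfamily ages ship as editable literature-derived placeholders; only the
<12.5 My hominoid cut is semantically load-bearing.
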