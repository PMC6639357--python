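# demethyl1

Locus-level analyses of transposable-element (TE) activation after global
DNA demethylation in human neural progenitor cells (hNPCs), built for the
experimental design in which *DNMT1*, the maintenance DNA
methyltransferase, is knocked out by CRISPR-Cas9 and the consequences are
read out by whole-genome bisulfite sequencing (WGBS), stranded paired-end
RNA-seq, ChIP-seq, and amplicon sequencing of the CRISPR target site.

The scientific core: passive demethylation de-represses evolutionarily
young, hominoid-specific LINE-1 (L1) retrotransposons — subfamilies younger
than 12.5 million years (L1HS, L1PA2, L1PA3) — in the sense orientation,
while older L1s and other TE classes stay silent. The demethylated young
L1s gain active-promoter chromatin (H3K27ac, Pol II at their 5′ UTR) and
act as alternative promoters: transcripts initiate inside the (usually
antisense-oriented) L1 and splice into exons of nearby protein-coding
genes, detectable as TE–exon fusion reads and as coordinated upregulation
of genes within 50 kb of activated elements.

## What the package implements

| module | analysis |
|---|---|
| `annotations` | RepeatMasker-style TE tables, GTF gene models, FLI-L1 (full-length intact L1, >6 kb with intact ORF1/ORF2/5′UTR/3′UTR) classification, subfamily ages with the <12.5 My hominoid cut, exclusion of exon-overlapping TEs before quantification |
| `methylome` | Bismark-style per-cytosine calls; mean mCpG/CpG over regions and 1-kb tiles with the ≥3× coverage rule; genome-wide CpG and non-CpG levels (read-weighted and site-mean) |
| `te_expression` | unique-fragment locus-level TE counting (largest-overlap assignment), the ≥5-reads-across-samples filter, median-of-ratios and library-scaling normalization, a calibrated negative-binomial Wald test with BH correction, sense/antisense counting over FLI-L1s |
| `fusion` | TE–TSS promoter candidates (TSS of a protein-coding transcript inside an L1/LTR12C) and fusion-read detection: a fragment overlapping both a TE and a coding exon, sense to the gene, with split-read or spanning-pair evidence |
| `proximity` | genes within 50 kb of upregulated elements, and the Wilcoxon rank-sum shift of their log2 fold changes against background genes |
| `crispr` | amplicon indel calling across a flanked cut site, left-aligned canonical unique indels with frequencies, frameshift/in-frame classification (net length mod 3), % modified |
| `chip` | MAPQ-filtered CPM coverage tracks, replicate means and log2(IP/input) ratios, strand-flipped scale-regions heatmap matrices anchored at element 5′ ends |
| `simulate` | a fully seeded synthetic hNPC dataset (genome, annotations, methylomes, RNA/ChIP/amplicon alignments) with machine-readable ground truth for every stage |

The differential test is a deliberate re-implementation of the
median-ratio / negative-binomial approach: per-feature method-of-moments
dispersions are shrunk toward a fitted a₀ + a₁/μ trend and the Wald
statistic is referred to a moderated-t null; it is validated by type-I and
power calibration rather than by matching another tool's output bit for
bit.

## Worked example

Generate the default synthetic dataset and run the methylation and
expression stages:

```python
from demethyl1 import annotations as ann, methylome as meth, te_expression as texp
from demethyl1.simulate import Simulation, SimulationConfig

sim = Simulation(SimulationConfig(seed=42))
sim.simulate_all("demo/")

for cond in ("control", "ko"):
    calls = meth.calls_table(meth.read_methylation_calls(f"demo/methylation.{cond}.CpG.cov"))
    print(cond, round(100 * meth.global_methylation(calls).weighted, 1))
# control 79.2
# ko 7.9

frags = ann.parse_te_annotation("demo/te_annotation.bed")
te_set = ann.filter_nonexonic(frags, ann.parse_gtf("demo/genes.gtf"))
sams = {f"{c}_{r}": f"demo/rnaseq.{c}_{r}.sam" for c in ("control", "ko") for r in (1, 2, 3)}
matrix = texp.filter_min_total(texp.quantify_samples(sams, te_set, "reverse-stranded"))
de = texp.differential_test(matrix, {s: s.split("_")[0] for s in sams},
                            normalization="library-scaling", reference="control")
print((de["direction"] == "up").sum(), "of", len(de), "tested elements upregulated")
# 32 of 51 tested elements upregulated
```

The 32 upregulated loci are exactly the planted hominoid-specific L1
copies: control hNPCs sit at ~79% CpG methylation, the knockout at ~8%,
and only the young L1 subfamilies respond. The same dataset yields 100%
recall with zero false positives on the planted fusion fragments, a
93.6% amplicon modification rate across 12 unique indels, and an H3K27ac
metaprofile that is 5′-peaked over young L1s (5′-quarter contrast ≈ 1.9)
but flat (≈ 0.02) over old L1s, HERVs and SVAs.

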