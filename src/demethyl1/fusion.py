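"""TE alternative-promoter candidates and TE-exon fusion reads.

A promoter candidate is an (element, transcript) pair where the annotated
TSS of a protein-coding transcript falls inside an L1 or LTR12C element. A
fusion read is a fragment whose alignment touches both a TE and an exon of
a protein-coding gene in sense orientation relative to the gene; the TE-side
orientation is unrestricted, which is what makes antisense L1 promoters
detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotations import TEFragment, TranscriptModel
from .te_expression import ReadFragment, _overlap_bp

DEFAULT_PROMOTER_SUBFAMILY_PREFIXES = ("L1", "LTR12C")


@dataclass(frozen=True)
class PromoterCandidate:
    fragment: TEFragment
    transcript: TranscriptModel
    orientation: str  # TE strand relative to gene strand: "sense"/"antisense"


@dataclass(frozen=True)
class FusionRead:
    query_id: str
    te_element_id: str
    gene_id: str
    gene_sense: bool
    te_orientation: str  # "sense"/"antisense", fragment strand vs TE strand
    evidence: str  # "split-read" or "spanning-pair"


def restrict_promoter_subfamilies(
    te_set: Iterable[TEFragment],
    prefixes: Sequence[str] = DEFAULT_PROMOTER_SUBFAMILY_PREFIXES,
) -> list[TEFragment]:
    return [te for te in te_set if any(te.subfamily.startswith(p) for p in prefixes)]


def find_te_tss_overlaps(
    transcripts: Iterable[TranscriptModel],
    te_set: Sequence[TEFragment],
) -> list[PromoterCandidate]:
    """One candidate per (element, transcript) pair whose TSS base lies in
    the element interval (half-open). Transcripts must already be restricted
    to protein-coding; non-coding ones are ignored defensively."""
    trees: dict[str, IntervalTree] = {}
    for te in te_set:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te)
    out: list[PromoterCandidate] = []
    for tx in transcripts:
        if not tx.coding:
            continue
        tree = trees.get(tx.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.at(tx.tss), key=lambda iv: (iv.begin, iv.data.element_id)):
            te = iv.data
            orientation = "sense" if te.strand == tx.strand else "antisense"
            out.append(PromoterCandidate(te, tx, orientation))
    return out


def detect_fusion_reads(
    fragments: Iterable[ReadFragment],
    te_set: Sequence[TEFragment],
    transcripts: Sequence[TranscriptModel],
    min_overlap_bp: int = 1,
    gene_side: str = "exon",
) -> list[FusionRead]:
    """Scan fragments for TE-exon fusion evidence.

    A fragment is retained iff (a) >= ``min_overlap_bp`` aligned bases
    overlap a TE, (b) as many overlap an exon (or the transcript span when
    ``gene_side="span"``) of a protein-coding gene, and (c) the fragment
    strand equals the gene strand. When one mate's spliced blocks provide
    both overlaps the evidence is ``split-read``, otherwise
    ``spanning-pair``. The TE with the largest fragment overlap and the
    gene with the largest exon overlap are recorded.
    """
    if gene_side not in ("exon", "span"):
        raise ValueError("gene_side must be 'exon' or 'span'")
    te_trees: dict[str, IntervalTree] = {}
    for te in te_set:
        te_trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te)
    gene_trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        if not tx.coding:
            continue
        tree = gene_trees.setdefault(tx.chrom, IntervalTree())
        if gene_side == "exon":
            for s, e in tx.exons:
                tree.addi(s, e, tx)
        else:
            tree.addi(*tx.span, tx)

    out: list[FusionRead] = []
    for frag in fragments:
        if frag.fragment_strand is None:
            raise ValueError("detect_fusion_reads requires a stranded protocol")
        te_tree = te_trees.get(frag.chrom)
        gene_tree = gene_trees.get(frag.chrom)
        if te_tree is None or gene_tree is None:
            continue

        union = frag.union_blocks()
        te_hits: dict[str, int] = {}
        gene_hits: dict[str, int] = {}
        te_by_mate: list[set[str]] = [set(), set()]
        gene_by_mate: list[set[str]] = [set(), set()]
        te_objs: dict[str, TEFragment] = {}
        for mi, blocks in enumerate((frag.blocks1, frag.blocks2)):
            for s, e in blocks:
                for iv in te_tree.overlap(s, e):
                    te = iv.data
                    te_hits[te.element_id] = _overlap_bp(union, te.start, te.end)
                    te_objs[te.element_id] = te
                    te_by_mate[mi].add(te.element_id)
                for iv in gene_tree.overlap(s, e):
                    tx = iv.data
                    if tx.strand != frag.fragment_strand:
                        continue  # sense-to-gene filter
                    if gene_side == "exon":
                        ov = sum(_overlap_bp(union, xs, xe) for xs, xe in tx.exons)
                    else:
                        ov = _overlap_bp(union, *tx.span)
                    gene_hits[tx.gene_id] = max(gene_hits.get(tx.gene_id, 0), ov)
                    gene_by_mate[mi].add(tx.gene_id)
        te_hits = {k: v for k, v in te_hits.items() if v >= min_overlap_bp}
        gene_hits = {k: v for k, v in gene_hits.items() if v >= min_overlap_bp}
        if not te_hits or not gene_hits:
            continue
        te_id = max(sorted(te_hits), key=lambda k: te_hits[k])
        gene_id = max(sorted(gene_hits), key=lambda k: gene_hits[k])
        split = any(
            te_id in te_by_mate[mi] and gene_id in gene_by_mate[mi] for mi in (0, 1)
        )
        te = te_objs[te_id]
        out.append(
            FusionRead(
                query_id=frag.query_id,
                te_element_id=te_id,
                gene_id=gene_id,
                gene_sense=True,
                te_orientation="sense" if frag.fragment_strand == te.strand else "antisense",
                evidence="split-read" if split else "spanning-pair",
            )
        )
    return sorted(out, key=lambda r: (r.gene_id, r.te_element_id, r.query_id))


def fusion_matrix(
    fusion_reads_per_sample: Mapping[str, Sequence[FusionRead]],
    promoter_candidates: Sequence[PromoterCandidate],
    library_sizes: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Gene x sample fusion-read counts, restricted to genes whose annotated
    TSS overlaps a TE, library-scaling normalized when library sizes are
    given."""
    allowed = sorted({c.transcript.gene_id for c in promoter_candidates})
    samples = list(fusion_reads_per_sample)
    mat = pd.DataFrame(0.0, index=pd.Index(allowed, name="gene_id"), columns=samples)
    for sample, reads in fusion_reads_per_sample.items():
        for r in reads:
            if r.gene_id in mat.index:
                mat.loc[r.gene_id, sample] += 1
    if library_sizes is not None:
        libs = pd.Series(library_sizes).reindex(samples).astype(float)
        mat = mat.div(libs / libs.mean(), axis=1)
    return mat


def write_fusion_reads(reads: Iterable[FusionRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tte_element_id\tgene_id\tgene_sense\tte_orientation\tevidence\n")
        for r in reads:
            fh.write(
                f"{r.query_id}\t{r.te_element_id}\t{r.gene_id}\t"
                f"{int(r.gene_sense)}\t{r.te_orientation}\t{r.evidence}\n"
            )
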