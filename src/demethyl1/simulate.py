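"""Synthetic "demethylated hNPC" dataset generator.

Produces a toy two-chromosome genome carrying age-stratified L1 copies (low
divergence for young subfamilies, high for old), Alu/HERV/LTR12C/SVA
stand-ins, and protein-coding genes; Bismark-style methylation call files
for a highly methylated control and a demethylated KO condition; stranded
paired-end RNA alignments where hominoid-specific L1s are activated
sense-only in the KO and designed genes gain antisense-L1-promoter fusion
fragments; ChIP alignments with H3K27ac/Pol II enrichment at activated L1
5' ends; and CRISPR amplicon reads carrying a diverse indel spectrum at a
cut site. Machine-readable ground truth accompanies every stage.

Defaults encode the study conditions: control CpG methylation mean 0.79 vs
0.079 in the KO, non-CpG level 0.004 in both, ~10x per-site coverage,
activation log2FC +4 (sense only), 3 RNA replicates per group, 2 ChIP
replicates, editing rate 0.935. Everything is bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .annotations import (
    IntactnessFlags,
    TEFragment,
    TranscriptModel,
    write_te_annotation,
)
from .crispr import IndelEvent, canonicalize
from .proximity import genes_near_elements

# fixed stream ids so each stage owns an independent, order-insensitive RNG
_RNG_GENOME = 1
_RNG_METH = {"control": 2, "ko": 3}
_RNG_RNA = {"control": 10, "ko": 20}
_RNG_CHIP = 30
_RNG_AMPLICON = 40

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    class_: str
    family: str
    age_my: float | None
    n_copies: int
    consensus_len: int
    full_length_fraction: float
    divergence_mean_pct: float
    control_mean: float  # NB mean fragments / replicate / copy, control
    activated: bool  # KO boost applies (hominoid L1s in the default design)
    chrom: str


def default_subfamilies() -> list[SubfamilySpec]:
    """The default TE complement: three hominoid L1 subfamilies (activated
    in the KO), older L1s, and SINE/LTR/SVA stand-ins that stay silent."""
    return [
        SubfamilySpec("L1HS", "LINE", "L1", 3.1, 12, 6100, 0.6, 1.37, 2.0, True, "chr1"),
        SubfamilySpec("L1PA2", "LINE", "L1", 7.6, 10, 6100, 0.5, 2.8, 2.0, True, "chr1"),
        SubfamilySpec("L1PA3", "LINE", "L1", 12.4, 10, 6100, 0.4, 4.5, 2.0, True, "chr1"),
        SubfamilySpec("L1PA7", "LINE", "L1", 30.0, 12, 6100, 0.3, 10.0, 0.3, False, "chr1"),
        SubfamilySpec("L1M5", "LINE", "L1", 80.0, 14, 6000, 0.1, 20.0, 0.3, False, "chr1"),
        SubfamilySpec("AluY", "SINE", "Alu", 18.0, 30, 300, 1.0, 2.0, 0.8, False, "chr2"),
        SubfamilySpec("HERVK", "LTR", "ERVK", 35.0, 8, 6000, 0.5, 8.0, 0.3, False, "chr2"),
        SubfamilySpec("LTR12C", "LTR", "ERV1", 40.0, 8, 1500, 1.0, 8.0, 0.3, False, "chr2"),
        SubfamilySpec("SVA_D", "SVA", "SVA", 9.0, 10, 1600, 1.0, 3.0, 0.3, False, "chr2"),
    ]


@dataclass
class SimulationConfig:
    seed: int = 42
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    subfamilies: list[SubfamilySpec] = field(default_factory=default_subfamilies)
    # genes
    n_plain_genes_chr1: int = 7
    n_plain_genes_chr2: int = 20
    n_fusion_genes: int = 3
    exon_len: int = 300
    intron_len: int = 800
    n_exons: int = 4
    # genes carry the bulk of the library (as in poly-A mRNA-seq), so
    # sample-wise library scaling reflects depth rather than TE activation
    gene_control_mean: float = 200.0
    near_gene_log2fc: float = 1.5
    near_gene_window_bp: int = 50_000
    # methylome
    cpg_mean: dict[str, float] = field(
        default_factory=lambda: {"control": 0.79, "ko": 0.079}
    )
    beta_concentration: float = 8.0
    ch_level: float = 0.004
    coverage_mean: float = 10.0
    n_cpg_sites: int = 10_000
    n_ch_sites: int = 4_000
    # RNA
    n_replicates: int = 3
    activation_log2fc: float = 4.0
    nb_dispersion: float = 0.05
    fragment_len: int = 300
    read_len: int = 150
    multimap_fraction: float = 0.25  # of hominoid-L1 fragments, NH=2
    fusion_fragments_per_gene: int = 10
    # ChIP
    chip_background_reads: int = 40_000
    chip_reads_per_activated_element: int = 60
    chip_read_len: int = 50
    chip_utr5_bp: int = 900
    n_chip_replicates: int = 2
    lowmapq_fraction: float = 0.02
    # amplicon
    amplicon_len: int = 1400
    cut_pos: int = 700
    n_amplicon_reads: int = 5_000
    editing_rate: float = 0.935
    n_unique_indels: int = 12
    insertion_fraction: float = 0.25
    deletion_size_geom_p: float = 0.3
    amplicon_read_len: int = 400


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, float]:
    """Substitute bases at the given per-base rate; returns the mutated copy
    and the realized divergence percentage."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        idx = np.nonzero(hit)[0]
        cur = np.searchsorted(BASES, out[idx])
        out[idx] = BASES[(cur + shift) % 4]
    return out, 100.0 * n_hit / seq.size


@dataclass
class Annotation:
    te_fragments: list[TEFragment]
    transcripts: list[TranscriptModel]
    intactness: dict[str, IntactnessFlags]


@dataclass
class GroundTruth:
    element_info: dict[str, dict]
    activated_element_ids: list[str]
    fli_l1_ids: list[str]
    fusion_genes: dict[str, str]  # gene_id -> promoter element_id
    near_gene_ids: list[str]
    methylation_truth: dict[str, float]
    rna_unique_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    library_sizes: dict[str, int] = field(default_factory=dict)
    fusion_fragment_ids: dict[str, list[str]] = field(default_factory=dict)
    chip_enriched_ids: list[str] = field(default_factory=list)
    indel_spectrum: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class Simulation:
    """Stateful generator: build the genome first, then any of the assay
    simulators, in any order; all randomness derives from the config seed
    via fixed per-stage streams."""

    def __init__(self, config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()
        self.genome: dict[str, np.ndarray] = {}
        self.annotation: Annotation | None = None
        self.truth: GroundTruth | None = None
        self._occupied: dict[str, list[tuple[int, int]]] = {}

    # ------------------------------------------------------------------
    # genome + annotations

    def _reserve(self, rng, chrom: str, length: int, margin: int = 200,
                 min_start: int | None = None) -> int:
        size = self.config.chrom_sizes[chrom]
        taken = self._occupied.setdefault(chrom, [])
        lo = max(margin, min_start or 0)
        for _ in range(2000):
            start = int(rng.integers(lo, size - length - margin))
            if all(start - margin >= e or start + length + margin <= s for s, e in taken):
                taken.append((start, start + length))
                return start
        raise RuntimeError(f"could not place a {length} bp feature on {chrom}; genome too small")

    def simulate_genome_and_annotations(self) -> tuple[dict[str, np.ndarray], Annotation, GroundTruth]:
        cfg = self.config
        rng = _rng(cfg, _RNG_GENOME)
        self.genome = {c: _random_seq(rng, n) for c, n in cfg.chrom_sizes.items()}
        self._occupied = {}
        consensi = {s.name: _random_seq(rng, s.consensus_len) for s in cfg.subfamilies}

        te_fragments: list[TEFragment] = []
        intactness: dict[str, IntactnessFlags] = {}
        element_info: dict[str, dict] = {}
        activated: list[str] = []
        fli_ids: list[str] = []

        def plant_copy(spec: SubfamilySpec, idx: int, chrom: str, full: bool,
                       start: int | None = None, strand: str | None = None) -> TEFragment:
            cons = consensi[spec.name]
            if full:
                copy_seq = cons
            else:
                tlen = int(rng.integers(500, min(4500, spec.consensus_len - 1)))
                copy_seq = cons[-tlen:]  # 5'-truncated, keeps the 3' end
            copy_seq, realized_div = _mutate(rng, copy_seq, spec.divergence_mean_pct / 100.0)
            if strand is None:
                strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
                copy_seq = np.array([comp[bytes(b)] for b in copy_seq[::-1]], dtype="S1")
            if start is None:
                start = self._reserve(rng, chrom, copy_seq.size)
            else:
                self._occupied.setdefault(chrom, []).append((start, start + copy_seq.size))
            self.genome[chrom][start:start + copy_seq.size] = copy_seq
            eid = f"{spec.name}_{idx:03d}"
            frag = TEFragment(eid, chrom, start, start + copy_seq.size, strand,
                              spec.name, spec.class_, spec.family, round(realized_div, 2))
            te_fragments.append(frag)
            intact = bool(full and spec.family == "L1" and rng.random() < 0.8)
            intactness[eid] = IntactnessFlags(intact, intact, intact, intact)
            element_info[eid] = {
                "subfamily": spec.name, "class": spec.class_, "age_my": spec.age_my,
                "full_length": full, "intact": intact, "divergence_pct": frag.divergence_pct,
                "chrom": chrom, "start": start, "end": start + copy_seq.size, "strand": strand,
            }
            if spec.activated:
                activated.append(eid)
            if intact and copy_seq.size > 6000:
                fli_ids.append(eid)
            return frag

        # genes first on chr1 so fusion promoters can anchor on their TSSs
        transcripts: list[TranscriptModel] = []
        fusion_genes: dict[str, str] = {}
        gene_len = cfg.n_exons * cfg.exon_len + (cfg.n_exons - 1) * cfg.intron_len

        def plant_gene(gid: str, chrom: str, strand: str | None = None,
                       upstream_reserve: int = 0) -> TranscriptModel:
            if strand is None:
                strand = "+" if rng.random() < 0.5 else "-"
            start = upstream_reserve + self._reserve(
                rng, chrom, gene_len + upstream_reserve, margin=400
            )
            exons = tuple(
                (start + i * (cfg.exon_len + cfg.intron_len),
                 start + i * (cfg.exon_len + cfg.intron_len) + cfg.exon_len)
                for i in range(cfg.n_exons)
            )
            tx = TranscriptModel(gid, f"{gid}.t1", chrom, strand, exons, True)
            transcripts.append(tx)
            return tx

        l1hs = next(s for s in cfg.subfamilies if s.name == "L1HS")
        for i in range(cfg.n_fusion_genes):
            gid = f"geneF{i:02d}"
            tx = plant_gene(gid, "chr1", strand="+",
                            upstream_reserve=l1hs.consensus_len + 100)
            # antisense full-length L1HS whose interval contains the TSS base
            l1_start = tx.tss - l1hs.consensus_len + 1
            frag = plant_copy(l1hs, 900 + i, "chr1", full=True, start=l1_start, strand="-")
            fusion_genes[gid] = frag.element_id
        for i in range(cfg.n_plain_genes_chr1):
            plant_gene(f"geneA{i:02d}", "chr1")
        for i in range(cfg.n_plain_genes_chr2):
            plant_gene(f"geneB{i:02d}", "chr2")

        for spec in cfg.subfamilies:
            n_full = int(round(spec.full_length_fraction * spec.n_copies))
            for i in range(spec.n_copies):
                plant_copy(spec, i, spec.chrom, full=i < n_full)

        te_fragments.sort(key=lambda f: (f.chrom, f.start))
        self.annotation = Annotation(te_fragments, transcripts, intactness)

        activated_frags = [f for f in te_fragments if f.element_id in set(activated)]
        near = genes_near_elements(transcripts, activated_frags, cfg.near_gene_window_bp)
        near_ids = sorted({a.gene_id for a in near})

        self.truth = GroundTruth(
            element_info=element_info,
            activated_element_ids=sorted(activated),
            fli_l1_ids=sorted(fli_ids),
            fusion_genes=fusion_genes,
            near_gene_ids=near_ids,
            methylation_truth={
                "cpg_control": cfg.cpg_mean["control"],
                "cpg_ko": cfg.cpg_mean["ko"],
                "ch_both": cfg.ch_level,
            },
        )
        return self.genome, self.annotation, self.truth

    # ------------------------------------------------------------------
    # methylome

    def simulate_methylome(self, condition: str, outdir) -> dict[str, Path]:
        """Write Bismark-style coverage files (0-based half-open dialect)
        for CpG and CH contexts under one condition."""
        cfg = self.config
        if condition not in cfg.cpg_mean:
            raise ValueError(f"unknown condition {condition!r}")
        rng = _rng(cfg, _RNG_METH[condition])
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        cpg_sites, ch_sites = [], []
        for chrom in sorted(self.genome):
            seq = self.genome[chrom]
            is_c = seq[:-1] == b"C"
            is_g_next = seq[1:] == b"G"
            cpg = np.nonzero(is_c & is_g_next)[0]
            ch = np.nonzero(is_c & ~is_g_next)[0]
            cpg_sites.append((chrom, cpg))
            ch_sites.append((chrom, ch))

        def subsample(per_chrom, n_target):
            total = sum(len(p) for _, p in per_chrom)
            out = []
            for chrom, pos in per_chrom:
                k = min(len(pos), int(round(n_target * len(pos) / total)))
                keep = np.sort(rng.choice(pos, size=k, replace=False))
                out.append((chrom, keep))
            return out

        mean = cfg.cpg_mean[condition]
        conc = cfg.beta_concentration
        paths = {}
        for context, per_chrom, n_target in (
            ("CpG", subsample(cpg_sites, cfg.n_cpg_sites), cfg.n_cpg_sites),
            ("CH", subsample(ch_sites, cfg.n_ch_sites), cfg.n_ch_sites),
        ):
            path = outdir / f"methylation.{condition}.{context}.cov"
            with open(path, "w") as fh:
                for chrom, pos in per_chrom:
                    cov = rng.poisson(cfg.coverage_mean, size=pos.size)
                    if context == "CpG":
                        p = rng.beta(mean * conc, (1 - mean) * conc, size=pos.size)
                    else:
                        p = np.full(pos.size, cfg.ch_level)
                    meth = rng.binomial(cov, p)
                    for j in range(pos.size):
                        if cov[j] == 0:
                            continue
                        pct = 100.0 * meth[j] / cov[j]
                        fh.write(
                            f"{chrom}\t{pos[j]}\t{pos[j] + 1}\t{pct:.4f}\t"
                            f"{meth[j]}\t{cov[j] - meth[j]}\n"
                        )
            paths[context] = path
        return paths

    # ------------------------------------------------------------------
    # RNA-seq

    def _sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unsorted"},
                "SQ": [{"SN": c, "LN": n} for c, n in self.config.chrom_sizes.items()],
            }
        )

    @staticmethod
    def _cigar_from_blocks(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        cig = []
        for i, (s, e) in enumerate(blocks):
            if i:
                cig.append((3, s - blocks[i - 1][1]))  # N gap
            cig.append((0, e - s))  # M
        return cig

    def _emit_pair(self, out, header, qname, chrom, left_blocks, right_blocks,
                   transcript_strand, nh=1, mapq=255):
        """Write one properly paired dUTP fragment: mate order on the
        reference is (left, right); the sense mate is read 2."""
        tid = list(self.config.chrom_sizes).index(chrom)
        if transcript_strand == "+":
            flags = (163, 83)  # left = R2 forward, right = R1 reverse
        else:
            flags = (99, 147)  # left = R1 forward, right = R2 reverse
        for blocks, flag, mate_blocks in (
            (left_blocks, flags[0], right_blocks),
            (right_blocks, flags[1], left_blocks),
        ):
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = tid
            a.reference_start = blocks[0][0]
            a.mapping_quality = mapq if nh == 1 else 3
            a.cigar = self._cigar_from_blocks(blocks)
            a.next_reference_id = tid
            a.next_reference_start = mate_blocks[0][0]
            tlen = max(b[1] for b in left_blocks + right_blocks) - left_blocks[0][0]
            a.template_length = tlen if flag in (99, 163) else -tlen
            a.set_tag("NH", nh)
            out.write(a)

    def simulate_rnaseq(self, condition: str, outdir) -> dict[str, Path]:
        """Write one SAM per replicate; records planted unique TE counts,
        library sizes, and fusion fragment ids into the ground truth."""
        cfg = self.config
        if self.annotation is None:
            raise RuntimeError("simulate_genome_and_annotations first")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = self._sam_header()
        specs = {s.name: s for s in cfg.subfamilies}
        near = set(self.truth.near_gene_ids)
        paths = {}
        for rep in range(cfg.n_replicates):
            rng = _rng(cfg, _RNG_RNA[condition] + rep)
            sample = f"{condition}_{rep + 1}"
            path = outdir / f"rnaseq.{sample}.sam"
            unique_counts: dict[str, int] = {}
            n_frag = 0
            qcount = 0
            fusion_ids: list[str] = []
            with pysam.AlignmentFile(str(path), "w", header=header) as out:
                # TE-derived fragments, element-sense only
                for te in self.annotation.te_fragments:
                    spec = specs[te.subfamily]
                    mean = spec.control_mean
                    if spec.activated and condition == "ko":
                        mean *= 2.0 ** cfg.activation_log2fc
                    unique_counts[te.element_id] = 0
                    if mean <= 0:
                        continue
                    n = rng.negative_binomial(
                        1.0 / cfg.nb_dispersion,
                        1.0 / (1.0 + cfg.nb_dispersion * mean),
                    )
                    n_unique = 0
                    hominoid = spec.family == "L1" and spec.age_my is not None and spec.age_my < 12.5
                    for _ in range(int(n)):
                        if te.length > cfg.fragment_len:
                            s = int(rng.integers(te.start, te.end - cfg.fragment_len))
                        else:
                            # short element: fragment centred on it
                            s = te.start - (cfg.fragment_len - te.length) // 2
                        multi = hominoid and rng.random() < cfg.multimap_fraction
                        qcount += 1
                        n_frag += 1
                        if not multi:
                            n_unique += 1
                        self._emit_pair(
                            out, header, f"{sample}.te{qcount:07d}", te.chrom,
                            [(s, s + cfg.read_len)],
                            [(s + cfg.fragment_len - cfg.read_len, s + cfg.fragment_len)],
                            te.strand, nh=1 if not multi else 2,
                        )
                    unique_counts[te.element_id] = n_unique
                # gene mRNA fragments (spliced; blocks confined to exons)
                for tx in self.annotation.transcripts:
                    gene_stream = 100_000 + zlib.crc32(tx.gene_id.encode()) % 100_000
                    gfac = float(np.exp(0.4 * _rng(cfg, gene_stream).normal()))
                    mean = cfg.gene_control_mean * gfac
                    if condition == "ko" and tx.gene_id in near:
                        mean *= 2.0 ** cfg.near_gene_log2fc
                    n = rng.negative_binomial(
                        1.0 / cfg.nb_dispersion,
                        1.0 / (1.0 + cfg.nb_dispersion * mean),
                    )
                    tx_len = sum(e - s for s, e in tx.exons)
                    for _ in range(int(n)):
                        t0 = int(rng.integers(1, tx_len - cfg.fragment_len))
                        left = self._tx_to_blocks(tx, t0, t0 + cfg.read_len)
                        right = self._tx_to_blocks(
                            tx, t0 + cfg.fragment_len - cfg.read_len, t0 + cfg.fragment_len
                        )
                        if tx.strand == "-":
                            left, right = right, left
                        qcount += 1
                        n_frag += 1
                        self._emit_pair(
                            out, header, f"{sample}.gx{qcount:07d}", tx.chrom,
                            left, right, tx.strand,
                        )
                # fusion fragments: KO only, spliced from inside the
                # antisense promoter L1 into exon 2, sense to the gene
                if condition == "ko":
                    for gid, eid in sorted(self.truth.fusion_genes.items()):
                        tx = next(t for t in self.annotation.transcripts if t.gene_id == gid)
                        e2s = tx.exons[1][0]
                        for k in range(cfg.fusion_fragments_per_gene):
                            qcount += 1
                            n_frag += 1
                            qname = f"{sample}.fu{qcount:07d}"
                            fusion_ids.append(qname)
                            left = [(tx.tss - 200, tx.tss - 100), (e2s, e2s + 50)]
                            right = [(e2s + 50, e2s + 200)]
                            self._emit_pair(out, header, qname, tx.chrom, left, right, "+")
            self.truth.rna_unique_counts[sample] = unique_counts
            self.truth.library_sizes[sample] = n_frag
            self.truth.fusion_fragment_ids[sample] = fusion_ids
            paths[sample] = path
        return paths

    @staticmethod
    def _tx_to_blocks(tx: TranscriptModel, t0: int, t1: int) -> list[tuple[int, int]]:
        """Map a transcript-coordinate interval (genomic 5'->3' exon order)
        to genomic blocks."""
        blocks = []
        off = 0
        for s, e in tx.exons:
            elen = e - s
            lo = max(t0 - off, 0)
            hi = min(t1 - off, elen)
            if hi > lo:
                blocks.append((s + lo, s + hi))
            off += elen
        return blocks

    # ------------------------------------------------------------------
    # ChIP + amplicons

    def _chip_targets(self) -> list[TEFragment]:
        act = set(self.truth.activated_element_ids)
        return [
            f for f in self.annotation.te_fragments
            if f.element_id in act and f.length >= 2000
        ]

    def simulate_chip(self, outdir) -> dict[str, Path]:
        """H3K27ac / Pol II / input SAMs for both conditions; KO IP samples
        carry extra reads over activated-L1 5' regions."""
        cfg = self.config
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = self._sam_header()
        targets = self._chip_targets()
        self.truth.chip_enriched_ids = sorted(t.element_id for t in targets)
        chrom_names = list(cfg.chrom_sizes)
        sizes = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=float)
        pchrom = sizes / sizes.sum()
        paths = {}
        stream = _RNG_CHIP
        for mark in ("H3K27ac", "PolII", "input"):
            n_rep = 1 if mark == "input" else cfg.n_chip_replicates
            for condition in ("control", "ko"):
                for rep in range(n_rep):
                    stream += 1
                    rng = _rng(cfg, stream)
                    name = f"chip.{mark}.{condition}.rep{rep + 1}"
                    path = outdir / f"{name}.sam"
                    with pysam.AlignmentFile(str(path), "w", header=header) as out:
                        nb = cfg.chip_background_reads
                        ci = rng.choice(len(chrom_names), size=nb, p=pchrom)
                        frac = rng.random(nb)
                        lowq = rng.random(nb) < cfg.lowmapq_fraction
                        i = 0
                        for k in range(nb):
                            chrom = chrom_names[ci[k]]
                            pos = int(frac[k] * (cfg.chrom_sizes[chrom] - cfg.chip_read_len))
                            i += 1
                            self._emit_single(out, header, f"{name}.bg{i:07d}", chrom, pos,
                                              cfg.chip_read_len, rng, 5 if lowq[k] else 30)
                        if mark != "input" and condition == "ko":
                            for te in targets:
                                lo = te.start if te.strand == "+" else te.end - cfg.chip_utr5_bp
                                hi = lo + cfg.chip_utr5_bp - cfg.chip_read_len
                                for _ in range(cfg.chip_reads_per_activated_element):
                                    pos = int(rng.integers(lo, hi))
                                    i += 1
                                    self._emit_single(out, header, f"{name}.en{i:07d}",
                                                      te.chrom, pos, cfg.chip_read_len, rng, 30)
                    paths[name] = path
        return paths

    def _emit_single(self, out, header, qname, chrom, pos, length, rng, mapq):
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = 16 if rng.random() < 0.5 else 0
        a.reference_id = list(self.config.chrom_sizes).index(chrom)
        a.reference_start = pos
        a.mapping_quality = mapq
        a.cigar = [(0, length)]
        out.write(a)

    def _draw_indel_spectrum(self, rng, reference: str) -> list[tuple[IndelEvent, float]]:
        cfg = self.config
        events: dict[tuple, IndelEvent] = {}
        guard = 0
        while True:
            while len(events) < cfg.n_unique_indels:
                guard += 1
                if guard > 10_000:
                    raise RuntimeError("could not draw a unique indel spectrum")
                pos = cfg.cut_pos + int(rng.integers(-6, 3))
                if rng.random() < cfg.insertion_fraction:
                    length = int(min(1 + rng.geometric(0.5), 12))
                    alt = "".join(rng.choice(list("ACGT"), size=length))
                    ev = IndelEvent("insertion", pos, "", alt)
                else:
                    length = int(min(1 + rng.geometric(cfg.deletion_size_geom_p), 25))
                    ev = IndelEvent("deletion", pos, reference[pos:pos + length], "")
                ev = canonicalize(ev, reference)
                # keep events safely inside the default +/-10 bp window
                if ev.pos < cfg.cut_pos - 9 or ev.pos + len(ev.ref_allele) > cfg.cut_pos + 9:
                    continue
                events[ev.key()] = ev
            classes = {e.net_length % 3 == 0 for e in events.values()}
            if len(classes) == 2:
                break
            events.pop(next(iter(events)))  # force a redraw until both frame classes occur
        ordered = sorted(events.values(), key=lambda e: e.key())
        w = 0.8 ** np.arange(len(ordered))
        w /= w.sum()
        return list(zip(ordered, w.tolist()))

    def simulate_amplicons(self, outdir) -> dict[str, Path]:
        """Amplicon reference FASTA + aligned reads carrying the planted
        indel spectrum at the cut site."""
        cfg = self.config
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rng = _rng(cfg, _RNG_AMPLICON)
        ref = "".join(np.char.decode(_random_seq(rng, cfg.amplicon_len).astype("S1")))
        fasta = outdir / "amplicon.fa"
        with open(fasta, "w") as fh:
            fh.write(">amplicon\n")
            for i in range(0, len(ref), 70):
                fh.write(ref[i:i + 70] + "\n")
        spectrum = self._draw_indel_spectrum(rng, ref)
        self.truth.indel_spectrum = [
            {"kind": e.kind, "pos": e.pos, "ref": e.ref_allele, "alt": e.alt_allele,
             "net_length": e.net_length, "frequency": w}
            for e, w in spectrum
        ]
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "unsorted"},
             "SQ": [{"SN": "amplicon", "LN": cfg.amplicon_len}]}
        )
        sam = outdir / "amplicon.sam"
        probs = np.array([w for _, w in spectrum])
        rl = cfg.amplicon_read_len
        with pysam.AlignmentFile(str(sam), "w", header=header) as out:
            for i in range(cfg.n_amplicon_reads):
                a = pysam.AlignedSegment(header)
                a.query_name = f"amp{i:06d}"
                a.flag = 0
                a.reference_id = 0
                a.mapping_quality = 60
                if rng.random() < 0.05:  # uninformative: does not span the window
                    a.reference_start = 0
                    a.cigar = [(0, 200)]
                    a.query_sequence = ref[:200]
                    out.write(a)
                    continue
                start = int(rng.integers(cfg.cut_pos - 300, cfg.cut_pos - 60))
                a.reference_start = start
                if rng.random() < cfg.editing_rate:
                    ev = spectrum[int(rng.choice(len(spectrum), p=probs))][0]
                    lead = ev.pos - start
                    if ev.kind == "deletion" or (ev.kind == "complex" and not ev.alt_allele):
                        dlen = len(ev.ref_allele)
                        tail = rl - lead
                        a.cigar = [(0, lead), (2, dlen), (0, tail)]
                        a.query_sequence = ref[start:ev.pos] + ref[ev.pos + dlen:ev.pos + dlen + tail]
                    else:
                        ilen = len(ev.alt_allele)
                        tail = rl - lead - ilen
                        a.cigar = [(0, lead), (1, ilen), (0, tail)]
                        a.query_sequence = ref[start:ev.pos] + ev.alt_allele + ref[ev.pos:ev.pos + tail]
                else:
                    a.cigar = [(0, rl)]
                    a.query_sequence = ref[start:start + rl]
                out.write(a)
        return {"fasta": fasta, "sam": sam}

    # ------------------------------------------------------------------

    def simulate_all(self, outdir) -> dict[str, object]:
        """Run every stage and write the complete dataset plus ground-truth
        JSON under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.simulate_genome_and_annotations()
        self.write_genome(outdir)
        paths: dict[str, object] = {}
        for cond in ("control", "ko"):
            paths[f"methylome_{cond}"] = self.simulate_methylome(cond, outdir)
            paths[f"rnaseq_{cond}"] = self.simulate_rnaseq(cond, outdir)
        paths["chip"] = self.simulate_chip(outdir)
        paths["amplicon"] = self.simulate_amplicons(outdir)
        self.truth.to_json(outdir / "truth.json")
        paths["truth"] = outdir / "truth.json"
        return paths

    def write_genome(self, outdir) -> None:
        outdir = Path(outdir)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom in self.genome:
                fh.write(f">{chrom}\n")
                seq = "".join(np.char.decode(self.genome[chrom].astype("S1")))
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        write_te_annotation(self.annotation.te_fragments, outdir / "te_annotation.bed")
        with open(outdir / "genes.gtf", "w") as fh:
            for tx in self.annotation.transcripts:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_biotype "protein_coding";'
                )
                s0, e0 = tx.span
                fh.write(f"{tx.chrom}\tsim\ttranscript\t{s0 + 1}\t{e0}\t.\t{tx.strand}\t.\t{attrs}\n")
                for s, e in tx.exons:
                    fh.write(f"{tx.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n")
        with open(outdir / "intactness.tsv", "w") as fh:
            fh.write("element_id\torf1_intact\torf2_intact\tutr5_intact\tutr3_intact\n")
            for eid, fl in sorted(self.annotation.intactness.items()):
                fh.write(
                    f"{eid}\t{int(fl.orf1_intact)}\t{int(fl.orf2_intact)}\t"
                    f"{int(fl.utr5_intact)}\t{int(fl.utr3_intact)}\n"
                )
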