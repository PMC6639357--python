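"""TE and gene annotation models.

Parses RepeatMasker-derived TE tables and GTF gene models, classifies
full-length intact L1s (FLI-L1s), assigns evolutionary ages to L1
subfamilies, and applies the exon-overlap exclusion used before locus-level
TE quantification.

Coordinates are 0-based half-open throughout; GTF (1-based inclusive) is
converted at the parser boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

TE_CLASSES = frozenset({"LINE", "SINE", "LTR", "SVA"})

#: Age (million years) below which an L1 subfamily counts as hominoid-specific.
HOMINOID_AGE_CUTOFF_MY = 12.5

#: Literature-derived placeholder ages (My) for common L1 subfamilies.  Only
#: the <12.5 My hominoid cut is biologically load-bearing; edit freely.
DEFAULT_L1_AGES_MY: dict[str, float] = {
    "L1HS": 3.1,
    "L1PA2": 7.6,
    "L1PA3": 12.4,
    "L1PA4": 18.0,
    "L1PA5": 20.4,
    "L1PA6": 26.8,
    "L1PA7": 30.0,
    "L1PA8": 40.0,
    "L1M5": 80.0,
}


@dataclass(frozen=True)
class TEFragment:
    """One annotated transposable-element locus."""

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    class_: str
    family: str
    divergence_pct: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.element_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.element_id}: bad strand {self.strand!r}")
        if self.class_ not in TE_CLASSES:
            raise ValueError(f"{self.element_id}: class {self.class_!r} not in {sorted(TE_CLASSES)}")
        if self.divergence_pct < 0:
            raise ValueError(f"{self.element_id}: negative divergence")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SubfamilyAge:
    subfamily: str
    age_my: float
    hominoid_specific: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.age_my <= 0:
            raise ValueError("age_my must be > 0")
        if self.hominoid_specific is None:
            object.__setattr__(
                self, "hominoid_specific", self.age_my < HOMINOID_AGE_CUTOFF_MY
            )


def default_age_table() -> list[SubfamilyAge]:
    return [SubfamilyAge(s, a) for s, a in DEFAULT_L1_AGES_MY.items()]


@dataclass(frozen=True)
class IntactnessFlags:
    orf1_intact: bool = False
    orf2_intact: bool = False
    utr5_intact: bool = False
    utr3_intact: bool = False

    @property
    def all_intact(self) -> bool:
        return (
            self.orf1_intact and self.orf2_intact
            and self.utr5_intact and self.utr3_intact
        )


@dataclass(frozen=True)
class FliL1Record:
    """A full-length intact L1: >6 kb with intact ORF1, ORF2, 5'UTR and 3'UTR."""

    fragment: TEFragment
    length_bp: int
    orf1_intact: bool
    orf2_intact: bool
    utr5_intact: bool
    utr3_intact: bool


@dataclass(frozen=True)
class AgedFragment:
    """TE fragment annotated with subfamily age; ``age_my is None`` flags an
    unknown subfamily (counted in neither age group)."""

    fragment: TEFragment
    age_my: float | None
    hominoid_specific: bool | None


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding: bool

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        if any(a >= b for a, b in ex):
            raise ValueError(f"{self.transcript_id}: empty exon")
        if any(ex[i][1] > ex[i + 1][0] for i in range(len(ex) - 1)):
            raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def tss(self) -> int:
        """Strand-aware first transcribed base (0-based)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


FLI_MIN_LENGTH_BP = 6000


def parse_te_annotation(path, stats: dict | None = None) -> list[TEFragment]:
    """Read a BED-like TE table into :class:`TEFragment` records.

    Expected tab-separated columns: chrom, start, end, strand, subfamily,
    class, family, divergence_pct [, element_id]. Lines starting with ``#``
    or a ``chrom`` header are skipped. Rows whose class is outside
    {LINE, SINE, LTR, SVA} are dropped and counted (the analysis considers
    only those four classes); if a ``stats`` dict is supplied the count is
    stored under ``"excluded_class"``.
    """
    fragments: list[TEFragment] = []
    excluded = 0
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: line {lineno}: expected >=8 columns, got {len(fields)}")
            try:
                chrom, start, end, strand, subfam, cls, fam, div = fields[:8]
                start_i, end_i, div_f = int(start), int(end), float(div)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc
            if cls not in TE_CLASSES:
                excluded += 1
                continue
            elem_id = fields[8] if len(fields) > 8 else f"te{lineno:06d}"
            if elem_id in seen_ids:
                raise ValueError(f"{path}: line {lineno}: duplicate element_id {elem_id}")
            seen_ids.add(elem_id)
            fragments.append(
                TEFragment(elem_id, chrom, start_i, end_i, strand, subfam, cls, fam, div_f)
            )
    if excluded:
        logger.info("parse_te_annotation: dropped %d rows outside %s", excluded, sorted(TE_CLASSES))
    if stats is not None:
        stats["excluded_class"] = excluded
    return fragments


def classify_fli_l1(
    fragments: Iterable[TEFragment],
    feature_flags: Mapping[str, IntactnessFlags],
    min_length_bp: int = FLI_MIN_LENGTH_BP,
) -> list[FliL1Record]:
    """Classify full-length intact L1s.

    An element qualifies iff its genomic length exceeds ``min_length_bp``
    (default 6 kb) and ORF1, ORF2, 5'UTR and 3'UTR are all flagged intact.
    Fragments missing from ``feature_flags`` are treated as not intact and
    skipped with a warning.
    """
    out: list[FliL1Record] = []
    for frag in fragments:
        flags = feature_flags.get(frag.element_id)
        if flags is None:
            logger.warning("classify_fli_l1: no intactness flags for %s; treated as not intact", frag.element_id)
            continue
        if frag.length > min_length_bp and flags.all_intact:
            out.append(
                FliL1Record(
                    frag, frag.length,
                    flags.orf1_intact, flags.orf2_intact,
                    flags.utr5_intact, flags.utr3_intact,
                )
            )
    return out


def scan_orf_intactness(
    sequence: str,
    orf1_min_bp: int = 900,
    orf2_min_bp: int = 3500,
    utr5_min_bp: int = 700,
    utr3_min_bp: int = 100,
) -> IntactnessFlags:
    """Heuristic intactness scan of an element-sense L1 sequence.

    Looks for ATG-initiated stop-terminated open reading frames on the given
    strand; ORF1/ORF2 are called intact when a non-overlapping pair of ORFs
    of at least the configured lengths exists in order, the 5'UTR when at
    least ``utr5_min_bp`` precede the first such ORF, and the 3'UTR when at
    least ``utr3_min_bp`` follow the second. This deliberately encodes only
    coarse L1 anatomy; curated flags should be preferred when available.
    """
    from Bio.Seq import Seq

    seq = sequence.upper()
    orfs: list[tuple[int, int]] = []  # [start, end) in nucleotides
    for frame in range(3):
        prot = str(Seq(seq[frame:]).translate(to_stop=False))
        start = None
        for i, aa in enumerate(prot):
            if aa == "M" and start is None:
                start = i
            elif aa == "*" and start is not None:
                orfs.append((frame + 3 * start, frame + 3 * (i + 1)))
                start = None
    orfs.sort()
    best: tuple[int, int, int, int] | None = None
    for s1, e1 in orfs:
        if e1 - s1 < orf1_min_bp:
            continue
        for s2, e2 in orfs:
            if s2 >= e1 and e2 - s2 >= orf2_min_bp:
                best = (s1, e1, s2, e2)
                break
        if best:
            break
    if best is None:
        orf1 = any(e - s >= orf1_min_bp for s, e in orfs)
        orf2 = any(e - s >= orf2_min_bp for s, e in orfs)
        return IntactnessFlags(orf1, orf2, False, False)
    s1, e1, s2, e2 = best
    return IntactnessFlags(
        True, True, s1 >= utr5_min_bp, len(seq) - e2 >= utr3_min_bp
    )


def assign_subfamily_ages(
    fragments: Iterable[TEFragment],
    age_table: Sequence[SubfamilyAge] | None = None,
) -> list[AgedFragment]:
    """Annotate fragments with subfamily age and the hominoid-specific flag.

    Subfamilies absent from the table are flagged age-unknown (``None``),
    never fatal.
    """
    table = {a.subfamily: a for a in (age_table if age_table is not None else default_age_table())}
    out = []
    for frag in fragments:
        rec = table.get(frag.subfamily)
        if rec is None:
            out.append(AgedFragment(frag, None, None))
        else:
            out.append(AgedFragment(frag, rec.age_my, rec.hominoid_specific))
    return out


def exon_trees(transcripts: Iterable[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        tree = trees.setdefault(tx.chrom, IntervalTree())
        for s, e in tx.exons:
            tree.addi(s, e, tx.transcript_id)
    return trees


def filter_nonexonic(
    fragments: Iterable[TEFragment],
    transcripts: Iterable[TranscriptModel],
) -> list[TEFragment]:
    """Drop every TE fragment sharing >=1 bp with any annotated exon
    (strand-blind); half-open adjacency does not count as overlap."""
    trees = exon_trees(transcripts)
    out = []
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None or not tree.overlap(frag.start, frag.end):
            out.append(frag)
    return out


def parse_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file via gffutils.

    A transcript is ``coding`` when it owns a CDS feature or carries a
    ``protein_coding`` biotype attribute. GTF 1-based inclusive coordinates
    become 0-based half-open here.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    out: list[TranscriptModel] = []
    for tx in db.features_of_type("transcript"):
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(tx, featuretype="exon"))
        )
        if not exons:
            continue
        biotypes = set(tx.attributes.get("transcript_biotype", []))
        biotypes |= set(tx.attributes.get("gene_biotype", []))
        biotypes |= set(tx.attributes.get("transcript_type", []))
        has_cds = any(True for _ in db.children(tx, featuretype="CDS"))
        out.append(
            TranscriptModel(
                gene_id=tx.attributes["gene_id"][0],
                transcript_id=tx.attributes["transcript_id"][0],
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                coding=has_cds or "protein_coding" in biotypes,
            )
        )
    return out


def write_te_annotation(fragments: Iterable[TEFragment], path) -> None:
    """Write fragments back as the BED-like 9-column table accepted by
    :func:`parse_te_annotation`."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tsubfamily\tclass\tfamily\tdivergence_pct\telement_id\n")
        for f in fragments:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{f.subfamily}\t"
                f"{f.class_}\t{f.family}\t{f.divergence_pct:.2f}\t{f.element_id}\n"
            )
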