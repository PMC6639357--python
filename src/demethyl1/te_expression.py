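"""Locus-level TE and gene expression from uniquely mapped stranded pairs.

The quantification follows the analysis design for repeat loci: only
fragments whose alignment is unique (single best locus) are counted, each
fragment is assigned to the single TE locus with the largest base overlap,
elements with fewer than five fragments summed over all samples are dropped,
TE matrices are normalized by total genome-mapped fragments
(library-scaling) while gene matrices use the median-of-ratios method, and
differential expression is a negative-binomial Wald test with
trend-shrunken dispersions and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats as sps

from ._stats import bh_adjust, rank_sum_test
from .annotations import AgedFragment, FliL1Record, TEFragment

logger = logging.getLogger(__name__)

PROTOCOLS = ("reverse-stranded", "forward-stranded", "unstranded")
DEFAULT_MAPQ_UNIQUE = 10
MIN_TOTAL_DEFAULT = 5


@dataclass(frozen=True)
class ReadFragment:
    """One sequenced fragment (read pair) after alignment."""

    query_id: str
    chrom: str
    blocks1: tuple[tuple[int, int], ...]
    blocks2: tuple[tuple[int, int], ...]
    fragment_strand: str | None  # None under the unstranded protocol
    unique: bool
    mapq: int

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        return self.blocks1 + self.blocks2

    def union_blocks(self) -> list[tuple[int, int]]:
        """Merged, non-overlapping union of both mates' aligned blocks."""
        merged: list[list[int]] = []
        for s, e in sorted(self.blocks):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.blocks)

    @property
    def end(self) -> int:
        return max(e for _, e in self.blocks)


def _is_unique(read: pysam.AlignedSegment, mapq_min: int) -> bool:
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality >= mapq_min


def load_fragments(
    sam_path,
    protocol: str,
    mapq_min: int = DEFAULT_MAPQ_UNIQUE,
) -> Iterator[ReadFragment]:
    """Stream one :class:`ReadFragment` per properly paired template.

    Secondary/supplementary/unmapped records are ignored; orphan mates are
    counted and skipped. Fragment strand under the dUTP ("reverse-stranded")
    protocol is the strand of mate 2, i.e. opposite the strand of mate 1.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    pending: dict[str, pysam.AlignedSegment] = {}
    n_orphan = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or not read.is_proper_pair:
                n_orphan += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            if protocol == "reverse-stranded":
                strand = "+" if r1.is_reverse else "-"
            elif protocol == "forward-stranded":
                strand = "-" if r1.is_reverse else "+"
            else:
                strand = None
            yield ReadFragment(
                query_id=r1.query_name,
                chrom=r1.reference_name,
                blocks1=tuple(r1.get_blocks()),
                blocks2=tuple(r2.get_blocks()),
                fragment_strand=strand,
                unique=_is_unique(r1, mapq_min) and _is_unique(r2, mapq_min),
                mapq=min(r1.mapping_quality, r2.mapping_quality),
            )
    n_orphan += len(pending)
    if n_orphan:
        logger.info("load_fragments(%s): skipped %d orphan/unpaired records", sam_path, n_orphan)


@dataclass
class CountMatrix:
    """Features x samples fragment counts with per-sample library sizes
    (total genome-mapped fragments)."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def _te_tree(te_set: Sequence[TEFragment]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for te in te_set:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te)
    return trees


def _overlap_bp(blocks: Iterable[tuple[int, int]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in blocks)


def assign_fragment(
    frag: ReadFragment,
    trees: dict[str, IntervalTree],
    ambiguous: str = "largest-overlap",
) -> TEFragment | None:
    """Assign a fragment to one TE locus, strand-blind.

    ``largest-overlap`` picks the element with most overlapped bases over
    the union of the fragment's blocks (ties to the lower-coordinate
    element); ``discard`` drops fragments touching more than one element.
    """
    tree = trees.get(frag.chrom)
    if tree is None:
        return None
    blocks = frag.union_blocks()
    hits = set()
    for s, e in blocks:
        hits |= tree.overlap(s, e)
    if not hits:
        return None
    candidates = [iv.data for iv in hits]
    if len(candidates) == 1:
        return candidates[0]
    if ambiguous == "discard":
        return None
    scored = [
        (-_overlap_bp(blocks, te.start, te.end), te.start, te.element_id, te)
        for te in candidates
    ]
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def count_te_fragments(
    fragments: Iterable[ReadFragment],
    te_set: Sequence[TEFragment],
    ambiguous: str = "largest-overlap",
) -> tuple[pd.Series, int]:
    """Count unique fragments per TE locus for one sample.

    Returns ``(counts indexed by element_id, total fragments seen)``; the
    total (genome-mapped fragments, unique or not) is the library size used
    for sample-wise scaling. Non-unique fragments contribute to no element.
    """
    trees = _te_tree(te_set)
    counts = pd.Series(0, index=pd.Index([te.element_id for te in te_set], name="element_id"))
    n_total = 0
    for frag in fragments:
        n_total += 1
        if not frag.unique:
            continue
        te = assign_fragment(frag, trees, ambiguous=ambiguous)
        if te is not None:
            counts[te.element_id] += 1
    return counts, n_total


def quantify_samples(
    sam_paths: Mapping[str, object],
    te_set: Sequence[TEFragment],
    protocol: str,
    ambiguous: str = "largest-overlap",
) -> CountMatrix:
    """Build the TE count matrix over samples (sample name -> SAM path)."""
    cols, libs = {}, {}
    for sample, path in sam_paths.items():
        counts, n_total = count_te_fragments(
            load_fragments(path, protocol), te_set, ambiguous=ambiguous
        )
        cols[sample] = counts
        libs[sample] = n_total
    return CountMatrix(pd.DataFrame(cols), pd.Series(libs))


def count_gene_fragments(
    fragments: Iterable[ReadFragment],
    transcripts: Sequence["TranscriptModel"],
) -> tuple[pd.Series, int]:
    """Unique-fragment counts per gene by largest exon overlap (one sample).

    Companion to :func:`count_te_fragments` for the gene side of the
    analysis (median-ratio normalized downstream)."""
    trees: dict[str, IntervalTree] = {}
    gene_ids: list[str] = []
    for tx in transcripts:
        if tx.gene_id not in gene_ids:
            gene_ids.append(tx.gene_id)
        tree = trees.setdefault(tx.chrom, IntervalTree())
        for s, e in tx.exons:
            tree.addi(s, e, tx)
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"))
    n_total = 0
    for frag in fragments:
        n_total += 1
        if not frag.unique:
            continue
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        blocks = frag.union_blocks()
        best: tuple[int, str] | None = None
        seen: set[str] = set()
        for s, e in blocks:
            for iv in tree.overlap(s, e):
                tx = iv.data
                if tx.gene_id in seen:
                    continue
                seen.add(tx.gene_id)
                ov = sum(_overlap_bp(blocks, xs, xe) for xs, xe in tx.exons)
                if best is None or (-ov, tx.gene_id) < (-best[0], best[1]):
                    best = (ov, tx.gene_id)
        if best is not None:
            counts[best[1]] += 1
    return counts, n_total


def quantify_gene_samples(
    sam_paths: Mapping[str, object],
    transcripts: Sequence["TranscriptModel"],
    protocol: str,
) -> CountMatrix:
    cols, libs = {}, {}
    for sample, path in sam_paths.items():
        counts, n_total = count_gene_fragments(load_fragments(path, protocol), transcripts)
        cols[sample] = counts
        libs[sample] = n_total
    return CountMatrix(pd.DataFrame(cols), pd.Series(libs))


def filter_min_total(matrix: CountMatrix, min_total: int = MIN_TOTAL_DEFAULT) -> CountMatrix:
    """Drop features with fewer than ``min_total`` fragments summed over all
    samples (default 5)."""
    keep = matrix.counts.sum(axis=1) >= min_total
    return CountMatrix(matrix.counts.loc[keep], matrix.library_sizes)


def normalize(matrix: CountMatrix, mode: str) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors and the normalized matrix.

    ``median-ratio``: per-sample median of count / per-feature geometric
    mean over features with all-nonzero counts. ``library-scaling``:
    library_size / mean(library_size).
    """
    if mode == "median-ratio":
        counts = matrix.counts.to_numpy(dtype=float)
        all_nonzero = (counts > 0).all(axis=1)
        if not all_nonzero.any():
            raise ValueError(
                "median-ratio normalization needs at least one feature with "
                "nonzero counts in every sample; use library-scaling instead"
            )
        logc = np.log(counts[all_nonzero])
        log_geo = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - log_geo, axis=0))
        factors = pd.Series(sf, index=matrix.samples)
    elif mode == "library-scaling":
        libs = matrix.library_sizes.astype(float)
        factors = libs / libs.mean()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return factors, matrix.counts.div(factors, axis=1)


@dataclass
class DispersionFit:
    alpha_mom: np.ndarray
    alpha_trend: np.ndarray
    alpha: np.ndarray
    trend_coef: tuple[float, float]  # alpha(mu) = a0 + a1 / mu
    residual_df: int = 0


def estimate_dispersions(
    norm: np.ndarray,
    groups: np.ndarray,
    size_factors: np.ndarray,
    prior_df: float = 10.0,
) -> DispersionFit:
    """Per-feature NB dispersion: method-of-moments estimates shrunk toward
    a fitted a0 + a1/mean trend with ``prior_df`` pseudo-degrees of freedom.
    """
    labels = np.unique(groups)
    n, p = norm.shape[1], norm.shape[0]
    mean_all = norm.mean(axis=1)
    # pooled within-group variance of normalized counts
    ss = np.zeros(p)
    shot = np.zeros(p)  # expected Poisson (shot-noise) part of the variance
    df = 0
    for g in labels:
        cols = groups == g
        ng = int(cols.sum())
        if ng < 2:
            continue
        sub = norm[:, cols]
        mu_g = sub.mean(axis=1)
        ss += sub.var(axis=1, ddof=1) * (ng - 1)
        shot += mu_g * np.mean(1.0 / size_factors[cols]) * (ng - 1)
        df += ng - 1
    pooled_var = ss / max(df, 1)
    shot = shot / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (pooled_var - shot) / mean_all**2
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, 0.0)
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)

    # robust trend fit alpha = a0 + a1/mean over informative features
    ok = (mean_all > 0) & (alpha_mom > 1e-6)
    a0, a1 = 0.0, 0.0
    if ok.sum() >= 10:
        x = 1.0 / mean_all[ok]
        y = alpha_mom[ok]
        for _ in range(2):
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            pred = A @ coef
            resid = np.abs(y - pred)
            keep = resid <= 3 * np.median(resid) + 1e-12
            if keep.all():
                break
            x, y = x[keep], y[keep]
        a0, a1 = float(max(coef[0], 1e-6)), float(max(coef[1], 0.0))
    else:
        a0 = float(np.median(alpha_mom[ok])) if ok.any() else 0.01
    with np.errstate(divide="ignore"):
        alpha_trend = np.clip(a0 + a1 / np.maximum(mean_all, 1e-8), 1e-8, 10.0)

    # moment-scale shrinkage keeps the estimator unbiased under the trend
    alpha = (df * alpha_mom + prior_df * alpha_trend) / (df + prior_df)
    fit = DispersionFit(alpha_mom, alpha_trend, np.clip(alpha, 1e-8, 10.0), (a0, a1))
    fit.residual_df = df
    return fit


def differential_test(
    matrix: CountMatrix,
    groups: Mapping[str, str] | pd.Series,
    normalization: str = "library-scaling",
    reference: str | None = None,
    prior_df: float = 10.0,
    alpha_threshold: float = 0.05,
) -> pd.DataFrame:
    """Negative-binomial Wald test per feature (treatment vs reference).

    Group means are total-count estimates on the normalized scale with a
    Haldane-style half-fragment continuity total so an all-zero group still
    yields a finite log2 fold change. The Wald variance of each group's log
    mean is 1/(mu * S) + alpha * sum(s^2)/S^2 with S the summed size
    factors. BH adjustment excludes features whose p is undefined
    (all-zero in both groups).

    Returns a DataFrame indexed by feature with base_mean,
    log2_fold_change, p_value, p_adj and significant (p_adj < threshold).
    """
    groups = pd.Series(groups).reindex(matrix.samples)
    if groups.isna().any():
        raise ValueError("groups must cover every sample")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    ref = reference if reference is not None else labels[0]
    alt = [g for g in labels if g != ref][0]
    if (groups == ref).sum() < 2 or (groups == alt).sum() < 2:
        raise ValueError("need >=2 samples per group")

    sf, norm_df = normalize(matrix, normalization)
    counts = matrix.counts.to_numpy(dtype=float)
    norm = norm_df.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    grp = groups.to_numpy()

    fit = estimate_dispersions(norm, grp, s, prior_df=prior_df)
    alpha = fit.alpha

    def group_stats(label: str) -> tuple[np.ndarray, float, float]:
        cols = grp == label
        K = counts[:, cols].sum(axis=1)
        S = s[cols].sum()
        S2 = (s[cols] ** 2).sum()
        mu = (K + 0.5) / S
        return mu, S, S2

    mu_a, S_a, S2_a = group_stats(ref)
    mu_b, S_b, S2_b = group_stats(alt)
    base_mean = norm.mean(axis=1)

    var_ln = (
        1.0 / (mu_a * S_a) + alpha * S2_a / S_a**2
        + 1.0 / (mu_b * S_b) + alpha * S2_b / S_b**2
    )
    lfc = np.log2(mu_b / mu_a)
    z = np.log(mu_b / mu_a) / np.sqrt(var_ln)
    # moderated-t reference: the dispersion is estimated, not known, so the
    # Wald statistic gets residual + prior degrees of freedom
    t_df = fit.residual_df + prior_df
    pval = 2.0 * sps.t.sf(np.abs(z), df=t_df)
    # no information at all -> undefined p, excluded from BH
    undefined = counts.sum(axis=1) == 0
    pval[undefined] = np.nan
    padj = bh_adjust(pval)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "p_value": pval,
            "p_adj": padj,
        },
        index=matrix.features,
    )
    out["significant"] = out["p_adj"] < alpha_threshold
    out["direction"] = np.where(out["log2_fold_change"] > 0, "up", "down")
    out.loc[~out["significant"].fillna(False), "direction"] = "ns"
    return out


@dataclass(frozen=True)
class StrandedCount:
    element_id: str
    sense_count: int
    antisense_count: int


def strand_counts(
    fragments: Iterable[ReadFragment],
    fli_l1s: Sequence[FliL1Record],
) -> pd.DataFrame:
    """Per-element sense/antisense unique-fragment counts relative to the
    element strand. Requires a stranded protocol."""
    te_set = [r.fragment for r in fli_l1s]
    trees = _te_tree(te_set)
    sense = {te.element_id: 0 for te in te_set}
    anti = {te.element_id: 0 for te in te_set}
    for frag in fragments:
        if frag.fragment_strand is None:
            raise ValueError("strand_counts requires a stranded protocol")
        if not frag.unique:
            continue
        te = assign_fragment(frag, trees)
        if te is None:
            continue
        if frag.fragment_strand == te.strand:
            sense[te.element_id] += 1
        else:
            anti[te.element_id] += 1
    return pd.DataFrame(
        {
            "element_id": list(sense),
            "sense_count": list(sense.values()),
            "antisense_count": [anti[k] for k in sense],
        }
    ).set_index("element_id")


def sense_antisense_test(stranded: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparing per-element sense vs antisense
    counts (exact by enumeration for combined n <= 20)."""
    return rank_sum_test(
        stranded["sense_count"].to_numpy(dtype=float),
        stranded["antisense_count"].to_numpy(dtype=float),
    )


def subfamily_summary(
    de_results: pd.DataFrame,
    aged_fragments: Sequence[AgedFragment],
) -> pd.DataFrame:
    """Per-subfamily upregulated-element counts, ordered by evolutionary age
    (youngest first; age-unknown subfamilies last)."""
    meta = pd.DataFrame(
        {
            "element_id": [a.fragment.element_id for a in aged_fragments],
            "subfamily": [a.fragment.subfamily for a in aged_fragments],
            "age_my": [a.age_my if a.age_my is not None else np.nan for a in aged_fragments],
        }
    ).set_index("element_id")
    de = de_results.join(meta, how="inner")
    up = de["significant"].fillna(False) & (de["log2_fold_change"] > 0)
    agg = (
        de.assign(up=up)
        .groupby("subfamily")
        .agg(n_upregulated=("up", "sum"), age_my=("age_my", "first"))
    )
    totals = meta.groupby("subfamily").size().rename("n_total_elements")
    out = agg.join(totals)
    out["n_upregulated"] = out["n_upregulated"].astype(int)
    return out.sort_values("age_my", na_position="last").reset_index()
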