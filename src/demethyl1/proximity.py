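"""Expression shifts of protein-coding genes near upregulated TEs.

Genes whose body lies within a window (default 50 kb) of any significantly
upregulated element form the "near" set; their log2 fold changes are
compared with the remaining expressed genes by a two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .annotations import TEFragment, TranscriptModel

DEFAULT_WINDOW_BP = 50_000


@dataclass(frozen=True)
class ProximityAssignment:
    gene_id: str
    te_element_id: str
    distance_bp: int


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap or
    touch."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end, 0)


def _gene_interval(tx: TranscriptModel, mode: str) -> tuple[int, int]:
    if mode == "body":
        return tx.span
    if mode == "tss":
        return tx.tss, tx.tss + 1
    raise ValueError("mode must be 'body' or 'tss'")


def genes_near_elements(
    genes: Iterable[TranscriptModel],
    upregulated_tes: Sequence[TEFragment],
    window_bp: int = DEFAULT_WINDOW_BP,
    mode: str = "body",
) -> list[ProximityAssignment]:
    """Strand-blind nearest-element assignment.

    A gene is included iff the minimal gap between its interval (gene body
    by default, TSS point with ``mode="tss"``) and any qualifying element is
    <= ``window_bp``; the nearest element (ties to lower coordinate) and the
    distance are recorded. With several transcripts per gene the widest body
    span is used.
    """
    spans: dict[str, tuple[str, int, int]] = {}
    for tx in genes:
        s, e = _gene_interval(tx, mode)
        cur = spans.get(tx.gene_id)
        if cur is None:
            spans[tx.gene_id] = (tx.chrom, s, e)
        else:
            spans[tx.gene_id] = (cur[0], min(cur[1], s), max(cur[2], e))
    by_chrom: dict[str, list[TEFragment]] = {}
    for te in upregulated_tes:
        by_chrom.setdefault(te.chrom, []).append(te)
    out: list[ProximityAssignment] = []
    for gene_id in sorted(spans):
        chrom, gs, ge = spans[gene_id]
        best: tuple[int, int, str] | None = None
        for te in by_chrom.get(chrom, []):
            d = interval_gap(gs, ge, te.start, te.end)
            key = (d, te.start, te.element_id)
            if best is None or key < best:
                best = key
        if best is not None and best[0] <= window_bp:
            out.append(ProximityAssignment(gene_id, best[2], best[0]))
    return out


@dataclass(frozen=True)
class ShiftResult:
    mean_near: float | None
    mean_background: float | None
    statistic: float | None
    p_value: float | None
    n_near: int
    n_background: int

    @property
    def defined(self) -> bool:
        return self.p_value is not None


def expression_shift_test(
    gene_log2fc: pd.Series,
    near_gene_ids: Iterable[str],
) -> ShiftResult:
    """Compare log2FC of genes near upregulated elements vs all other
    (expressed) genes. ``gene_log2fc`` is indexed by gene id and should
    already be restricted to genes passing the expression filter."""
    near_ids = [g for g in set(near_gene_ids) if g in gene_log2fc.index]
    near = gene_log2fc.loc[near_ids].dropna()
    background = gene_log2fc.drop(index=near_ids).dropna()
    if len(near) == 0 or len(background) == 0:
        return ShiftResult(None, None, None, None, len(near), len(background))
    stat, p = rank_sum_test(near.to_numpy(), background.to_numpy())
    return ShiftResult(
        float(near.mean()), float(background.mean()), stat, p,
        len(near), len(background),
    )
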