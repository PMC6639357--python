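"""CpG / non-CpG methylation summaries from per-cytosine call files.

Input is the Bismark-style coverage dialect: tab-separated
``chrom  start  end  pct_meth  count_meth  count_unmeth`` with 0-based
half-open positions, one cytosine per line, position-sorted within each
chromosome. The percentage column is ignored in favour of the counts.

Two summary conventions are exposed everywhere: the mean of per-site
mCpG/CpG ratios (the default for regions and tiles, matching "each data
point is the mean mCpG/CpG ratio") and the read-weighted global fraction
sum(meth)/sum(meth+unmeth) (the default for genome-wide levels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_COVERAGE = 3


class CpGCall(NamedTuple):
    chrom: str
    pos: int  # 0-based position of the cytosine
    context: str  # "CG" or "CH"
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class MethylationSummary:
    region_id: str
    mean_ratio: float | None  # None when no qualifying site (undefined)
    n_sites_used: int

    @property
    def defined(self) -> bool:
        return self.mean_ratio is not None


@dataclass(frozen=True)
class GlobalMethylation:
    """Genome-wide methylation level in both conventions."""

    weighted: float | None  # sum(meth) / sum(coverage)
    site_mean: float | None  # mean of per-site ratios
    n_sites_used: int

    def value(self, method: str = "weighted") -> float | None:
        if method not in ("weighted", "site-mean"):
            raise ValueError(f"unknown method {method!r}")
        return self.weighted if method == "weighted" else self.site_mean


def read_methylation_calls(path, context: str = "CG") -> Iterator[CpGCall]:
    """Stream calls from a coverage file, enforcing sorted positions.

    Bismark emits one file per cytosine context, so the context is a
    parameter, not a column.
    """
    if context not in ("CG", "CH"):
        raise ValueError(f"context must be CG or CH, got {context!r}")
    last: dict[str, int] = {}
    done: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            chrom, start = fields[0], int(fields[1])
            n_meth, n_unmeth = int(fields[4]), int(fields[5])
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if chrom in done:
                raise ValueError(f"{path}: line {lineno}: unsorted input (chromosome {chrom} revisited); sort the file first")
            if chrom in last and start < last[chrom]:
                raise ValueError(f"{path}: line {lineno}: unsorted input; sort the file first")
            for c in list(last):
                if c != chrom:
                    done.add(c)
                    del last[c]
            last[chrom] = start
            yield CpGCall(chrom, start, context, n_meth, n_unmeth)


def calls_table(calls: Iterable[CpGCall]) -> pd.DataFrame:
    """Materialize a call stream as a DataFrame (chrom, pos, n_meth, n_unmeth,
    coverage, ratio)."""
    df = pd.DataFrame(calls, columns=["chrom", "pos", "context", "n_meth", "n_unmeth"])
    df["coverage"] = df["n_meth"] + df["n_unmeth"]
    with np.errstate(invalid="ignore"):
        df["ratio"] = df["n_meth"] / df["coverage"]
    return df


def _qualify(df: pd.DataFrame, min_coverage: int) -> pd.DataFrame:
    return df[df["coverage"] >= min_coverage]


def region_methylation(
    calls: Iterable[CpGCall] | pd.DataFrame,
    region: tuple[str, int, int],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    region_id: str | None = None,
) -> MethylationSummary:
    """Mean per-site mCpG/CpG ratio over one region.

    Only sites with coverage >= ``min_coverage`` (default 3x) contribute to
    either the mean or the site count. With zero qualifying sites the
    summary is flagged undefined.
    """
    chrom, start, end = region
    df = calls if isinstance(calls, pd.DataFrame) else calls_table(calls)
    sub = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    sub = _qualify(sub, min_coverage)
    rid = region_id if region_id is not None else f"{chrom}:{start}-{end}"
    if len(sub) == 0:
        return MethylationSummary(rid, None, 0)
    return MethylationSummary(rid, float(sub["ratio"].mean()), int(len(sub)))


def regions_methylation(
    calls: Iterable[CpGCall] | pd.DataFrame,
    regions: Sequence[tuple[str, str, int, int]],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[MethylationSummary]:
    """Vectorized :func:`region_methylation` over many (id, chrom, start, end)
    regions (e.g. all TE fragments)."""
    df = calls if isinstance(calls, pd.DataFrame) else calls_table(calls)
    df = _qualify(df, min_coverage)
    out: list[MethylationSummary] = []
    by_chrom = {c: g.sort_values("pos") for c, g in df.groupby("chrom")}
    for rid, chrom, start, end in regions:
        g = by_chrom.get(chrom)
        if g is None:
            out.append(MethylationSummary(rid, None, 0))
            continue
        pos = g["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        if hi <= lo:
            out.append(MethylationSummary(rid, None, 0))
        else:
            ratios = g["ratio"].to_numpy()[lo:hi]
            out.append(MethylationSummary(rid, float(ratios.mean()), int(hi - lo)))
    return out


def tile_methylation(
    calls: Iterable[CpGCall] | pd.DataFrame,
    genome_sizes: dict[str, int],
    tile_bp: int = 1000,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-tile mean ratios over non-overlapping ``tile_bp`` windows.

    Returns one row per tile genome-wide (chrom, tile_start, tile_end,
    mean_ratio, n_sites_used); tiles without qualifying sites carry NaN.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_table(calls)
    df = _qualify(df, min_coverage)
    frames = []
    for chrom, size in genome_sizes.items():
        n_tiles = int(np.ceil(size / tile_bp))
        starts = np.arange(n_tiles) * tile_bp
        tiles = pd.DataFrame({
            "chrom": chrom,
            "tile_start": starts,
            "tile_end": np.minimum(starts + tile_bp, size),
        })
        g = df[df["chrom"] == chrom]
        if len(g):
            idx = g["pos"].to_numpy() // tile_bp
            agg = pd.DataFrame({"idx": idx, "ratio": g["ratio"].to_numpy()}).groupby("idx")["ratio"].agg(["mean", "count"])
            tiles["mean_ratio"] = tiles.index.map(agg["mean"])
            tiles["n_sites_used"] = tiles.index.map(agg["count"]).fillna(0).astype(int)
        else:
            tiles["mean_ratio"] = np.nan
            tiles["n_sites_used"] = 0
        frames.append(tiles)
    return pd.concat(frames, ignore_index=True)


def global_methylation(
    calls: Iterable[CpGCall] | pd.DataFrame,
    context: str = "CG",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> GlobalMethylation:
    """Genome-wide methylation level for one cytosine context.

    Reports both the read-weighted fraction sum(meth)/sum(coverage) and the
    per-site-mean variant; pick with :meth:`GlobalMethylation.value`.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_table(calls)
    if "context" in df.columns:
        df = df[df["context"] == context]
    df = _qualify(df, min_coverage)
    if len(df) == 0:
        return GlobalMethylation(None, None, 0)
    weighted = float(df["n_meth"].sum() / df["coverage"].sum())
    return GlobalMethylation(weighted, float(df["ratio"].mean()), int(len(df)))


def write_region_summaries(summaries: Iterable[MethylationSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tmean_ratio\tn_sites_used\n")
        for s in summaries:
            val = "NA" if s.mean_ratio is None else f"{s.mean_ratio:.6f}"
            fh.write(f"{s.region_id}\t{val}\t{s.n_sites_used}\n")
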