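"""ChIP signal tracks and element-anchored metaprofile matrices.

Coverage is binned full-span read coverage after a MAPQ filter, scaled to
counts per million filtered reads. Tracks combine as replicate means or as
log2((IP + eps) / (input + eps)) ratios. Heatmap rows are elements with the
body rescaled to a fixed number of bins plus fixed-width flanks,
strand-flipped so the 5' end is always on the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from .annotations import TEFragment

DEFAULT_BIN_BP = 10
DEFAULT_MAPQ_MIN = 10
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class SignalTrack:
    bin_bp: int
    values: dict[str, np.ndarray]
    normalization: str  # raw-coverage / cpm / replicate-mean / log2-ratio

    def __post_init__(self) -> None:
        if self.bin_bp <= 0:
            raise ValueError("bin width must be positive")

    def chrom_bins(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def compatible(self, other: "SignalTrack") -> bool:
        return (
            self.bin_bp == other.bin_bp
            and set(self.values) == set(other.values)
            and all(self.values[c].shape == other.values[c].shape for c in self.values)
        )


def coverage_track(
    sam_path,
    genome_sizes: dict[str, int],
    bin_bp: int = DEFAULT_BIN_BP,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> SignalTrack:
    """Binned full-span read coverage, CPM-scaled.

    Reads with MAPQ below ``mapq_min`` (default 10, the unique-best-
    alignment filter) and secondary/supplementary records are excluded. Bin
    values are mean depth within the bin scaled by 1e6 / n_filtered_reads,
    so a track sums to 1e6 * read_span / bin_bp up to edge effects.
    """
    vals = {
        c: np.zeros(int(np.ceil(size / bin_bp)), dtype=float)
        for c, size in genome_sizes.items()
    }
    n_reads = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            arr = vals.get(read.reference_name)
            if arr is None:
                continue
            n_reads += 1
            s, e = read.reference_start, read.reference_end
            b0, b1 = s // bin_bp, (e - 1) // bin_bp
            if b0 == b1:
                arr[b0] += (e - s) / bin_bp
            else:
                arr[b0] += ((b0 + 1) * bin_bp - s) / bin_bp
                arr[b1] += (e - b1 * bin_bp) / bin_bp
                if b1 > b0 + 1:
                    arr[b0 + 1:b1] += 1.0
    if n_reads:
        for arr in vals.values():
            arr *= 1e6 / n_reads
    return SignalTrack(bin_bp, vals, "cpm")


def combine(
    tracks: Sequence[SignalTrack],
    mode: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SignalTrack:
    """Combine tracks: ``replicate-mean`` (element-wise mean of any number)
    or ``log2-ratio`` (exactly two tracks, IP then input, with
    pseudocount)."""
    if not tracks:
        raise ValueError("no tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.compatible(t):
            raise ValueError("tracks have mismatched binning")
    if mode == "replicate-mean":
        vals = {
            c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
        }
        return SignalTrack(first.bin_bp, vals, "replicate-mean")
    if mode == "log2-ratio":
        if len(tracks) != 2:
            raise ValueError("log2-ratio needs exactly (IP, input)")
        ip, inp = tracks
        vals = {
            c: np.log2((ip.values[c] + pseudocount) / (inp.values[c] + pseudocount))
            for c in first.values
        }
        return SignalTrack(first.bin_bp, vals, "log2-ratio")
    raise ValueError(f"unknown combine mode {mode!r}")


@dataclass
class MetaMatrix:
    matrix: np.ndarray  # elements x (flank_bins + body_bins + flank_bins)
    element_ids: list[str]
    body_bins: int
    flank_bins: int
    short_flagged: list[str] = field(default_factory=list)

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def _resample(values: np.ndarray, n_out: int) -> tuple[np.ndarray, bool]:
    """Average an array into ``n_out`` proportional windows; interpolate
    (flagged) when the input is shorter than the target."""
    n_in = values.size
    if n_in == 0:
        return np.zeros(n_out), True
    if n_in < n_out:
        x_out = np.linspace(0, n_in - 1, n_out) if n_in > 1 else np.zeros(n_out)
        return np.interp(x_out, np.arange(n_in), values), True
    csum = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.linspace(0, n_in, n_out + 1)
    totals = np.interp(edges, np.arange(n_in + 1), csum)
    widths = np.diff(edges)
    return np.diff(totals) / widths, False


def element_heatmap(
    track: SignalTrack,
    elements: Sequence[TEFragment],
    body_bins: int = 60,
    flank_bp: int = 1000,
    flank_bins: int = 10,
) -> MetaMatrix:
    """Scale-regions heatmap matrix: per element, upstream flank + scaled
    body + downstream flank, with minus-strand rows reversed so the 5' end
    is the left edge. Elements whose body holds fewer track bins than
    ``body_bins`` are interpolated and flagged."""
    rows = []
    ids = []
    flagged = []
    bb = track.bin_bp
    for te in elements:
        arr = track.values.get(te.chrom)
        if arr is None:
            continue
        n = arr.size

        def window(s: int, e: int, n_out: int) -> tuple[np.ndarray, bool]:
            b0 = max(0, s // bb)
            b1 = min(n, int(np.ceil(e / bb)))
            return _resample(arr[b0:b1], n_out)

        up, _ = window(te.start - flank_bp, te.start, flank_bins)
        body, short = window(te.start, te.end, body_bins)
        down, _ = window(te.end, te.end + flank_bp, flank_bins)
        row = np.concatenate([up, body, down])
        if te.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(te.element_id)
        if short:
            flagged.append(te.element_id)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * flank_bins + body_bins))
    return MetaMatrix(matrix, ids, body_bins, flank_bins, flagged)


def flip_minus_rows(matrix: MetaMatrix, elements: Sequence[TEFragment]) -> MetaMatrix:
    """Reverse rows of minus-strand elements (an involution: applying twice
    restores the original matrix)."""
    strand = {te.element_id: te.strand for te in elements}
    out = matrix.matrix.copy()
    for i, eid in enumerate(matrix.element_ids):
        if strand.get(eid) == "-":
            out[i] = out[i, ::-1]
    return MetaMatrix(out, list(matrix.element_ids), matrix.body_bins, matrix.flank_bins, list(matrix.short_flagged))


def five_prime_contrast(matrix: MetaMatrix) -> float:
    """Mean signal over the 5' quarter of the body minus the mean over the
    rest of the body. Near zero for a flat profile, strongly positive when
    signal concentrates at the 5' end (promoter-proximal enrichment)."""
    body = matrix.matrix[:, matrix.flank_bins:matrix.flank_bins + matrix.body_bins]
    q = max(1, matrix.body_bins // 4)
    prof = body.mean(axis=0)
    return float(prof[:q].mean() - prof[q:].mean())


def peak_bin_fraction(matrix: MetaMatrix, five_prime_cols: int | None = None) -> float:
    """Fraction of rows whose maximum falls within the first
    ``five_prime_cols`` columns after the upstream flank (default: the first
    quarter of the body). The 5'-peak statistic behind the young-L1
    metaprofile check."""
    if matrix.matrix.shape[0] == 0:
        return float("nan")
    if five_prime_cols is None:
        five_prime_cols = max(1, matrix.body_bins // 4)
    body = matrix.matrix[:, matrix.flank_bins:matrix.flank_bins + matrix.body_bins]
    argmax = body.argmax(axis=1)
    return float(np.mean(argmax < five_prime_cols))


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            for i, v in enumerate(arr):
                if v != 0:
                    fh.write(f"{chrom}\t{i * track.bin_bp}\t{(i + 1) * track.bin_bp}\t{v:.6g}\n")
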