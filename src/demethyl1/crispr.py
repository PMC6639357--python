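"""CRISPR amplicon indel diversity.

Calls insertion/deletion events from amplicon alignments across a flanked
cut-site window, left-aligns them through repeat context so equivalent
placements collapse to one canonical variant, tallies unique indels with
relative frequencies, classifies frame impact by net length mod 3, and
reports the overall modification rate.

Denominator rule: a read is informative only when its alignment spans the
whole flanked window, guarding against end-truncation artifacts. Reads with
substitutions only count as unmodified. Multiple indel operations on one
read inside the window collapse to a single complex event keyed by the full
local alternate haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

DEFAULT_FLANK_BP = 10

CIGAR_M, CIGAR_I, CIGAR_D = 0, 1, 2
REF_CONSUMING = {0, 2, 3, 7, 8}
QUERY_CONSUMING = {0, 1, 4, 7, 8}


@dataclass(frozen=True)
class IndelEvent:
    kind: str  # insertion / deletion / complex
    pos: int  # left-aligned 0-based reference position
    ref_allele: str
    alt_allele: str

    @property
    def net_length(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class IndelTally:
    event: IndelEvent
    read_count: int
    frequency: float
    frame_class: str  # "in-frame" iff net_length % 3 == 0 else "frameshift"


@dataclass(frozen=True)
class EditingSummary:
    total_reads: int  # informative reads (the denominator)
    modified_reads: int
    pct_modified: float
    n_unique_frameshift: int
    n_unique_inframe: int


def frame_class(net_length: int) -> str:
    return "in-frame" if net_length % 3 == 0 else "frameshift"


def call_read_indels(
    sam_path,
    cut_pos: int,
    flank_bp: int = DEFAULT_FLANK_BP,
    reference: str | None = None,
) -> tuple[dict[str, tuple[IndelEvent, ...]], int]:
    """Extract window-overlapping indel events per informative read.

    The window is ``[cut_pos - flank_bp, cut_pos + flank_bp)``. Returns
    ``(events by read name, number of informative reads)``; informative
    reads without events are present with an empty tuple (unmodified).
    Insertions are represented with empty ref allele, deletions with empty
    alt; >=2 window ops on one read merge into one complex event spanning
    from the first to the last op, with ref/alt taken over that span (needs
    ``reference`` for the complex ref allele; per-op calls take alleles
    from the read/CIGAR alone when the reference is not supplied, so plain
    deletions then carry a placeholder ref of the right length).
    """
    win_start, win_end = cut_pos - flank_bp, cut_pos + flank_bp
    per_read: dict[str, tuple[IndelEvent, ...]] = {}
    n_informative = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_start > win_start or read.reference_end < win_end:
                continue  # does not span the flanked window: uninformative
            n_informative += 1
            events = _events_from_cigar(read, win_start, win_end, reference)
            prev = per_read.get(read.query_name)
            if prev is None:
                per_read[read.query_name] = events
            else:
                # mates agree or the union is kept once per template
                per_read[read.query_name] = tuple(sorted(set(prev) | set(events), key=lambda e: e.key()))
                n_informative -= 1
    return per_read, n_informative


def _events_from_cigar(
    read: pysam.AlignedSegment,
    win_start: int,
    win_end: int,
    reference: str | None,
) -> tuple[IndelEvent, ...]:
    rpos = read.reference_start
    qpos = 0
    seq = read.query_sequence or ""
    raw: list[tuple[int, int, str, str]] = []  # (ref_start, ref_end, ref, alt)
    for op, length in read.cigartuples:
        if op == CIGAR_I:
            if win_start <= rpos <= win_end:
                raw.append((rpos, rpos, "", seq[qpos:qpos + length]))
        elif op == CIGAR_D:
            if rpos < win_end and rpos + length > win_start:
                if reference is not None:
                    ref_allele = reference[rpos:rpos + length]
                else:
                    ref_allele = "N" * length
                raw.append((rpos, rpos + length, ref_allele, ""))
        if op in REF_CONSUMING:
            rpos += length
        if op in QUERY_CONSUMING:
            qpos += length
    if not raw:
        return ()
    if len(raw) == 1:
        s, e, ref, alt = raw[0]
        kind = "insertion" if len(alt) > len(ref) else "deletion"
        return (IndelEvent(kind, s, ref, alt),)
    # merge into one complex event over the local span
    s = raw[0][0]
    e = max(r[1] for r in raw)
    if reference is None:
        raise ValueError("reference sequence required to merge complex events")
    alt = _query_over_ref_span(read, s, e)
    return (IndelEvent("complex", s, reference[s:e], alt),)


def _query_over_ref_span(read: pysam.AlignedSegment, span_start: int, span_end: int) -> str:
    """Read bases aligned over a reference span, including inserted bases."""
    rpos = read.reference_start
    qpos = 0
    seq = read.query_sequence or ""
    out: list[str] = []
    for op, length in read.cigartuples:
        consumes_r = op in REF_CONSUMING
        consumes_q = op in QUERY_CONSUMING
        if consumes_r and consumes_q:
            lo = max(rpos, span_start)
            hi = min(rpos + length, span_end)
            if hi > lo:
                out.append(seq[qpos + (lo - rpos):qpos + (hi - rpos)])
        elif consumes_q and not consumes_r:
            if span_start <= rpos <= span_end:
                out.append(seq[qpos:qpos + length])
        if consumes_r:
            rpos += length
        if consumes_q:
            qpos += length
    return "".join(out)


def canonicalize(event: IndelEvent, reference: str) -> IndelEvent:
    """Left-align an insertion or deletion through repeat context.

    Shifts the event to the smallest equivalent reference position; complex
    events are already keyed by their local haplotype and pass through
    unchanged. Raises when a deletion's ref allele disagrees with the
    reference.
    """
    if event.kind == "complex":
        return event
    pos = event.pos
    if event.kind == "deletion":
        ref = event.ref_allele
        if set(ref) == {"N"}:  # placeholder from reference-free calling
            ref = reference[pos:pos + len(ref)]
        if reference[pos:pos + len(ref)] != ref:
            raise ValueError(
                f"deletion at {pos} inconsistent with reference "
                f"({ref!r} vs {reference[pos:pos + len(ref)]!r})"
            )
        while pos > 0 and reference[pos - 1] == ref[-1]:
            pos -= 1
            ref = reference[pos:pos + len(ref)]
        return IndelEvent("deletion", pos, ref, "")
    if event.kind == "insertion":
        alt = event.alt_allele
        while pos > 0 and alt[-1] == reference[pos - 1]:
            alt = reference[pos - 1] + alt[:-1]
            pos -= 1
        return IndelEvent("insertion", pos, "", alt)
    raise ValueError(f"unknown event kind {event.kind!r}")


def tally_unique(
    per_read_events: Mapping[str, Sequence[IndelEvent]],
    n_informative: int,
    reference: str | None = None,
) -> tuple[list[IndelTally], EditingSummary]:
    """Group canonical events into unique indels with frequencies.

    Frequencies are relative to the informative-read denominator, so unique
    event frequencies plus the unmodified fraction sum to one. Frame class
    is net length mod 3 (complex events use their summed net length).
    """
    if n_informative <= 0:
        raise ValueError("zero informative reads")
    counts: dict[tuple[int, str, str], tuple[IndelEvent, int]] = {}
    n_modified = 0
    for _, events in sorted(per_read_events.items()):
        if not events:
            continue
        n_modified += 1
        ev = events[0]
        if reference is not None:
            ev = canonicalize(ev, reference)
        cur = counts.get(ev.key())
        counts[ev.key()] = (ev, 1 if cur is None else cur[1] + 1)
    tallies = [
        IndelTally(ev, n, n / n_informative, frame_class(ev.net_length))
        for ev, n in sorted(counts.values(), key=lambda t: (-t[1], t[0].key()))
    ]
    n_fs = sum(1 for t in tallies if t.frame_class == "frameshift")
    n_if = len(tallies) - n_fs
    summary = EditingSummary(
        total_reads=n_informative,
        modified_reads=n_modified,
        pct_modified=100.0 * n_modified / n_informative,
        n_unique_frameshift=n_fs,
        n_unique_inframe=n_if,
    )
    return tallies, summary


def write_tallies(tallies: Iterable[IndelTally], path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tref_allele\talt_allele\tkind\tnet_length\tread_count\tfrequency\tframe_class\n")
        for t in tallies:
            e = t.event
            fh.write(
                f"{e.pos}\t{e.ref_allele or '-'}\t{e.alt_allele or '-'}\t{e.kind}\t"
                f"{e.net_length}\t{t.read_count}\t{t.frequency:.6f}\t{t.frame_class}\n"
            )
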