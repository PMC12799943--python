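"""Core search: enumerate peptide splits, locate both arms in all six
reading frames of both strands, and classify the nucleotide gap between
the arms as a programmed ribosomal frameshifting (PRF) event.

The gap between a left-arm match ending at nucleotide ``e`` (exclusive)
and a right-arm match starting at ``r`` is ``r - e``:

* gap > 0 — the arms are spaced by that many nucleotides (forward
  slippage; PRF value reported with a plus sign, e.g. +2);
* gap < 0 — the arms' coding ranges overlap by ``|gap|`` nucleotides
  (backward slippage: nucleotides are read twice);
* gap == 0 — uninterrupted translation; reported once per contiguous
  full-length occurrence as a "Without frameshift" source, never as a
  two-arm event.

A single ``max_gap`` bound applies symmetrically (−max_gap … +max_gap).
Nonzero gaps divisible by 3 are real frameshift events with a same-frame
direction label (e.g. "1→1").
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .seqcore import (
    NucRecord,
    PepRecord,
    frame_of_offset,
    reverse_complement,
    translate,
)

__all__ = [
    "FORWARD",
    "REVERSE",
    "RunConfig",
    "SegmentOccurrence",
    "SourceEvent",
    "ContractError",
    "NothingToSearchError",
    "enumerate_splits",
    "find_occurrences",
    "pair_occurrences",
    "find_nonchimeric",
    "search",
]

FORWARD = "forward"
REVERSE = "reverse"

TYPE_FRAMESHIFT = "Frameshift"
TYPE_NO_FRAMESHIFT = "Without frameshift"


class ContractError(ValueError):
    """Occurrences passed to pairing violate the same-subject/strand contract."""


class NothingToSearchError(ValueError):
    """The query or subject list is empty."""


@dataclass(frozen=True)
class RunConfig:
    """User parameters of a search run.

    max_gap: symmetric bound on the PRF value in nucleotides (the
        analysis setting in the original study was 2).
    max_transcript_length: subjects longer than this are truncated in
        the report around the matched span.
    max_flanking_seq: nucleotides of context kept on each side when
        truncating.
    threads: worker count; results are merged into a canonical order so
        output is identical for any thread count.
    search_reverse: also search the reverse complement strand.
    """

    max_gap: int = 2
    max_transcript_length: int = 5000
    max_flanking_seq: int = 1000
    threads: int = 1
    search_reverse: bool = True

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be a positive integer")
        if self.max_transcript_length < 1:
            raise ValueError("max_transcript_length must be a positive integer")
        if self.max_flanking_seq < 0:
            raise ValueError("max_flanking_seq must be >= 0")
        if self.threads < 1:
            raise ValueError("threads must be a positive integer")


@dataclass(frozen=True)
class SegmentOccurrence:
    """Exact match of one peptide arm in one frame of one strand.

    Coordinates are 0-based half-open nucleotide positions on the
    *searched* strand (the reverse complement for reverse-strand hits).
    """

    subject_index: int
    strand: str
    nt_start: int
    nt_end: int
    aa_seq: str

    @property
    def frame(self) -> int:
        return frame_of_offset(self.nt_start)


@dataclass(frozen=True)
class SourceEvent:
    """One predicted source of a query peptide on one subject."""

    type_label: str
    frameshift_position: Optional[int]
    segment1: str
    segment2: str
    gap: int
    direction: Optional[tuple[int, int]]
    nucleotide_title: str
    protein_title: str
    protein_sequence: str
    frame_direction: str  # "Forward Frame" | "Reverse Frame"
    # internal bookkeeping (stable for tests; not part of the report)
    query_index: int = field(default=0, compare=False)
    subject_index: int = field(default=0, compare=False)
    strand: str = field(default=FORWARD, compare=False)
    left_nt_start: int = 0
    right_nt_start: Optional[int] = None
    span: tuple[int, int] = field(default=(0, 0), compare=False)

    @property
    def is_chimeric(self) -> bool:
        return self.type_label == TYPE_FRAMESHIFT


def _frame_direction_label(strand: str) -> str:
    return "Forward Frame" if strand == FORWARD else "Reverse Frame"


def enumerate_splits(peptide: PepRecord) -> list[tuple[str, str]]:
    """All two-arm splits of a peptide plus the full-sequence entry.

    Cut points run k = 1 … L−1 (left arm of one residue up to L−1
    residues), in ascending order; the full sequence with an empty
    right arm — used for the non-chimeric search — comes last.
    """
    s = peptide.seq
    splits = [(s[:k], s[k:]) for k in range(1, len(s))]
    splits.append((s, ""))
    return splits


def _searched_strand(subject: NucRecord, strand: str) -> str:
    if strand == FORWARD:
        return subject.seq
    if strand == REVERSE:
        return reverse_complement(subject.seq)
    raise ValueError(f"unknown strand {strand!r}")


def _occurrences_in_frames(
    arm: str,
    frames: Sequence[str],
    subject_index: int,
    strand: str,
) -> list[SegmentOccurrence]:
    """All (overlapping) exact hits of ``arm`` in three frame translations."""
    hits = []
    for frame_offset, aa in enumerate(frames):
        start = aa.find(arm)
        while start != -1:
            nt_start = frame_offset + 3 * start
            hits.append(
                SegmentOccurrence(
                    subject_index=subject_index,
                    strand=strand,
                    nt_start=nt_start,
                    nt_end=nt_start + 3 * len(arm),
                    aa_seq=arm,
                )
            )
            start = aa.find(arm, start + 1)
    hits.sort(key=lambda o: o.nt_start)
    return hits


def find_occurrences(
    arm: str,
    subject: NucRecord,
    strand: str = FORWARD,
    subject_index: int = 0,
) -> list[SegmentOccurrence]:
    """All exact occurrences of an arm in the three frames of one strand.

    Overlapping occurrences are all reported, in ascending ``nt_start``
    order.  Coordinates refer to the searched strand.
    """
    if not arm:
        raise ValueError("arm must be non-empty")
    searched = _searched_strand(subject, strand)
    frames = [translate(searched, f) for f in range(min(3, len(searched) + 1))]
    return _occurrences_in_frames(arm, frames, subject_index, strand)


def _build_event(
    left: SegmentOccurrence,
    right: SegmentOccurrence,
    gap: int,
    query: PepRecord,
    subject: NucRecord,
    query_index: int,
) -> SourceEvent:
    span = (
        min(left.nt_start, right.nt_start),
        max(left.nt_end, right.nt_end),
    )
    return SourceEvent(
        type_label=TYPE_FRAMESHIFT,
        frameshift_position=len(left.aa_seq),
        segment1=left.aa_seq,
        segment2=right.aa_seq,
        gap=gap,
        direction=(frame_of_offset(left.nt_start), frame_of_offset(right.nt_start)),
        nucleotide_title=subject.title,
        protein_title=query.title,
        protein_sequence=query.seq,
        frame_direction=_frame_direction_label(left.strand),
        query_index=query_index,
        subject_index=left.subject_index,
        strand=left.strand,
        left_nt_start=left.nt_start,
        right_nt_start=right.nt_start,
        span=span,
    )


def pair_occurrences(
    left: SegmentOccurrence,
    right: SegmentOccurrence,
    cfg: RunConfig,
    *,
    query: PepRecord,
    subject: NucRecord,
    query_index: int = 0,
) -> Optional[SourceEvent]:
    """Classify a left/right arm pairing as a PRF event, or reject it.

    Emits a Frameshift event iff the gap ``right.nt_start - left.nt_end``
    is nonzero and within ±max_gap.  A negative gap means the arms'
    codon ranges overlap by |gap| nt.  Gap 0 is handled by
    :func:`find_nonchimeric`, never here.
    """
    if left.subject_index != right.subject_index or left.strand != right.strand:
        raise ContractError(
            "left and right occurrences must come from the same subject and strand"
        )
    gap = right.nt_start - left.nt_end
    if gap == 0 or abs(gap) > cfg.max_gap:
        return None
    return _build_event(left, right, gap, query, subject, query_index)


def find_nonchimeric(
    peptide: PepRecord,
    subject: NucRecord,
    strand: str = FORWARD,
    subject_index: int = 0,
    query_index: int = 0,
) -> list[SourceEvent]:
    """One "Without frameshift" event per contiguous full-length match."""
    events = []
    for occ in find_occurrences(peptide.seq, subject, strand, subject_index):
        events.append(
            SourceEvent(
                type_label=TYPE_NO_FRAMESHIFT,
                frameshift_position=None,
                segment1=peptide.seq,
                segment2="",
                gap=0,
                direction=None,
                nucleotide_title=subject.title,
                protein_title=peptide.title,
                protein_sequence=peptide.seq,
                frame_direction=_frame_direction_label(strand),
                query_index=query_index,
                subject_index=subject_index,
                strand=strand,
                left_nt_start=occ.nt_start,
                right_nt_start=None,
                span=(occ.nt_start, occ.nt_end),
            )
        )
    return events


def _search_one_subject(
    subject_index: int,
    subject: NucRecord,
    queries: Sequence[PepRecord],
    cfg: RunConfig,
) -> list[SourceEvent]:
    events: list[SourceEvent] = []
    strands = [FORWARD] + ([REVERSE] if cfg.search_reverse else [])
    for strand in strands:
        searched = _searched_strand(subject, strand)
        frames = [translate(searched, f) for f in range(3)] if len(searched) >= 3 else []
        for qi, query in enumerate(queries):
            for seg1, seg2 in enumerate_splits(query):
                if not seg2:
                    # full-length contiguous search (gap 0)
                    for occ in _occurrences_in_frames(seg1, frames, subject_index, strand):
                        events.append(
                            SourceEvent(
                                type_label=TYPE_NO_FRAMESHIFT,
                                frameshift_position=None,
                                segment1=query.seq,
                                segment2="",
                                gap=0,
                                direction=None,
                                nucleotide_title=subject.title,
                                protein_title=query.title,
                                protein_sequence=query.seq,
                                frame_direction=_frame_direction_label(strand),
                                query_index=qi,
                                subject_index=subject_index,
                                strand=strand,
                                left_nt_start=occ.nt_start,
                                right_nt_start=None,
                                span=(occ.nt_start, occ.nt_end),
                            )
                        )
                    continue
                lefts = _occurrences_in_frames(seg1, frames, subject_index, strand)
                if not lefts:
                    continue
                rights = _occurrences_in_frames(seg2, frames, subject_index, strand)
                for left in lefts:
                    for right in rights:
                        gap = right.nt_start - left.nt_end
                        if gap == 0 or abs(gap) > cfg.max_gap:
                            continue
                        events.append(
                            _build_event(left, right, gap, query, subject, qi)
                        )
    return events


def _dedup_key(e: SourceEvent) -> tuple:
    return (
        e.protein_title,
        e.nucleotide_title,
        e.frame_direction,
        e.left_nt_start,
        e.frameshift_position,
        e.gap,
    )


def _sort_key(e: SourceEvent) -> tuple:
    return (
        e.query_index,
        e.subject_index,
        0 if e.strand == FORWARD else 1,
        e.left_nt_start,
        e.gap,
        e.frameshift_position if e.frameshift_position is not None else -1,
    )


def search(
    queries: Sequence[PepRecord],
    subjects: Sequence[NucRecord],
    cfg: Optional[RunConfig] = None,
) -> list[SourceEvent]:
    """Full search: every query against every subject, both strands.

    The result is the union over all queries × subjects × strands ×
    splits of arm pairings within the gap window plus contiguous
    full-length matches, deduplicated and in a deterministic total
    order (query input order, subject input order, forward strand
    first, left start, gap) regardless of thread count.
    """
    if cfg is None:
        cfg = RunConfig()
    if not queries or not subjects:
        raise NothingToSearchError("nothing to search: empty query or subject list")

    if cfg.threads > 1 and len(subjects) > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            chunks = pool.map(
                lambda item: _search_one_subject(item[0], item[1], queries, cfg),
                enumerate(subjects),
            )
            events = [e for chunk in chunks for e in chunk]
    else:
        events = [
            e
            for si, subject in enumerate(subjects)
            for e in _search_one_subject(si, subject, queries, cfg)
        ]

    seen: dict[tuple, SourceEvent] = {}
    for e in events:
        seen.setdefault(_dedup_key(e), e)
    out = list(seen.values())
    out.sort(key=_sort_key)
    return out
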