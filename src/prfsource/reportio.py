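"""FASTA ingestion, subject truncation, and the 12-column report.

The report is tab-separated by default (CSV optional) with one header
line and one line per predicted source.  Columns, in order:

    Type, Frameshift Position, Segment 1, Segment 2, Gap,
    Frameshift Direction, Nucleotide Title, Nucleotide Sequence,
    Protein Title, Protein Sequence, Frame Direction,
    Truncation for Nucleotide Sequence

Gap carries an explicit sign for positive values ("+2"), a minus for
negative ("-2"), and "0" for non-chimeric rows.  Frameshift Position
and Frameshift Direction are empty for "Without frameshift" rows.
For reverse-strand events the Nucleotide Sequence column reports the
subject in its input (forward) orientation; the Frame Direction column
signals the strand.
"""

from __future__ import annotations

import csv
import os
from dataclasses import astuple, dataclass
from typing import Iterable, Sequence

from .engine import FORWARD, RunConfig, SourceEvent
from .seqcore import NucRecord, PepRecord

__all__ = [
    "COLUMNS",
    "FastaParseError",
    "ReportRow",
    "read_fasta_nuc",
    "read_fasta_pep",
    "truncate_subject",
    "rows_from_events",
    "write_report",
    "read_report",
    "write_fasta",
]

COLUMNS = (
    "Type",
    "Frameshift Position",
    "Segment 1",
    "Segment 2",
    "Gap",
    "Frameshift Direction",
    "Nucleotide Title",
    "Nucleotide Sequence",
    "Protein Title",
    "Protein Sequence",
    "Frame Direction",
    "Truncation for Nucleotide Sequence",
)

ASCII_ARROW = "->"
UNICODE_ARROW = "→"


class FastaParseError(ValueError):
    """Malformed FASTA input; the message carries the 1-based line number."""


@dataclass(frozen=True)
class ReportRow:
    """One fully rendered report line (all fields already strings)."""

    type: str
    frameshift_position: str
    segment1: str
    segment2: str
    gap: str
    frameshift_direction: str
    nucleotide_title: str
    nucleotide_sequence: str
    protein_title: str
    protein_sequence: str
    frame_direction: str
    truncation: str

    def as_tuple(self) -> tuple[str, ...]:
        return astuple(self)


def _parse_fasta(path: str | os.PathLike) -> list[tuple[str, str, int]]:
    """Parse FASTA into (title, raw_sequence, header_line_number) triples."""
    records: list[tuple[str, str, int]] = []
    title: str | None = None
    title_line = 0
    chunks: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            n_lines = lineno
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                if title is not None:
                    if not chunks:
                        raise FastaParseError(
                            f"line {title_line}: record {title.split()[0]!r} has no sequence"
                        )
                    records.append((title, "".join(chunks), title_line))
                title = line[1:].strip()
                title_line = lineno
                chunks = []
                if not title:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
            else:
                if title is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
    if title is not None:
        if not chunks:
            raise FastaParseError(
                f"line {title_line}: record {title.split()[0]!r} has no sequence"
            )
        records.append((title, "".join(chunks), title_line))
    if not records:
        raise FastaParseError(f"line {max(n_lines, 1)}: no FASTA records in file")
    return records


def read_fasta_nuc(path: str | os.PathLike, unknown_to_n: bool = False) -> list[NucRecord]:
    """Read a nucleotide FASTA file, preserving input order.

    Titles are the full header line after '>'; multi-line sequences are
    joined.  Alphabet errors are reported with the record's header line.
    """
    out = []
    for title, raw, lineno in _parse_fasta(path):
        try:
            out.append(NucRecord.from_raw(title, raw, unknown_to_n))
        except ValueError as exc:
            raise FastaParseError(f"line {lineno}: record {title!r}: {exc}") from exc
    return out


def read_fasta_pep(path: str | os.PathLike) -> list[PepRecord]:
    """Read a peptide FASTA file with amino acid alphabet validation."""
    out = []
    for title, raw, lineno in _parse_fasta(path):
        try:
            out.append(PepRecord.from_raw(title, raw))
        except ValueError as exc:
            raise FastaParseError(f"line {lineno}: record {title!r}: {exc}") from exc
    return out


def write_fasta(records: Iterable[NucRecord | PepRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.title}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _forward_span(event: SourceEvent, subject_length: int) -> tuple[int, int]:
    """Matched span mapped to the input (forward) orientation."""
    start, end = event.span
    if event.strand == FORWARD:
        return start, end
    return subject_length - end, subject_length - start


def truncate_subject(
    subject: NucRecord, event: SourceEvent, cfg: RunConfig
) -> tuple[str, bool]:
    """Reported subject sequence for one event, truncated if too long.

    Subjects at or below ``max_transcript_length`` are reported whole.
    Longer subjects are cut to the union span of both arms extended by
    ``max_flanking_seq`` on each side (clipped at the sequence ends),
    always in the input orientation.
    """
    if subject.length <= cfg.max_transcript_length:
        return subject.seq, False
    start, end = _forward_span(event, subject.length)
    lo = max(0, start - cfg.max_flanking_seq)
    hi = min(subject.length, end + cfg.max_flanking_seq)
    return subject.seq[lo:hi], True


def _render_gap(gap: int) -> str:
    return f"+{gap}" if gap > 0 else str(gap)


def rows_from_events(
    events: Sequence[SourceEvent],
    subjects: Sequence[NucRecord],
    cfg: RunConfig,
    arrow: str = ASCII_ARROW,
) -> list[ReportRow]:
    """Render events (already deduplicated and canonically ordered) as rows."""
    rows = []
    for e in events:
        subject = subjects[e.subject_index]
        nuc_seq, truncated = truncate_subject(subject, e, cfg)
        rows.append(
            ReportRow(
                type=e.type_label,
                frameshift_position=(
                    str(e.frameshift_position) if e.frameshift_position is not None else ""
                ),
                segment1=e.segment1,
                segment2=e.segment2,
                gap=_render_gap(e.gap),
                frameshift_direction=(
                    f"{e.direction[0]}{arrow}{e.direction[1]}" if e.direction else ""
                ),
                nucleotide_title=e.nucleotide_title,
                nucleotide_sequence=nuc_seq,
                protein_title=e.protein_title,
                protein_sequence=e.protein_sequence,
                frame_direction=e.frame_direction,
                truncation="True" if truncated else "False",
            )
        )
    return rows


def write_report(
    rows: Sequence[ReportRow],
    path: str | os.PathLike,
    delimiter: str = "\t",
) -> None:
    """Write the 12-column report with a header line.

    The file is written atomically (temporary file + rename) so a
    failed run leaves no partial report behind.
    """
    tmp = f"{path}.tmp"
    try:
        with open(tmp, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            writer.writerow(COLUMNS)
            for row in rows:
                writer.writerow(row.as_tuple())
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_report(path: str | os.PathLike, delimiter: str = "\t") -> list[dict[str, str]]:
    """Re-parse a written report into one dict per row (tests, downstream use)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        return list(reader)
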