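"""Synthetic fixture and benchmark-set generator.

Reverse-translates peptides into host nucleotide sequences with planted
frameshift events of a chosen class, emulating the benchmark design of
the original study: per frameshift class in {−2, −1, 0, +1, +2}, a set
of random peptides is embedded, each in its own randomly padded subject,
and a truth table records every planted parameter.  The generator powers
all round-trip tests: the search engine must recover every planted event.

Construction rules
------------------
* Positive gap g: the two arms' codon runs are joined with g random
  nucleotides in between.
* Negative gap −g: the right arm's coding range starts g nt before the
  left arm's range ends, so the overlapping g nucleotides are shared.
  Boundary codons of both arms are chosen among synonymous codons so the
  overlap is consistent; when no synonymous combination exists (e.g. a
  left arm ending in Met followed by Met at overlap 1) the construction
  raises :class:`InfeasibleEventError` and the benchmark generator
  resamples the peptide.
* Gap 0: the whole peptide is encoded contiguously (a non-chimeric
  planting, recovered as a "Without frameshift" source).

Codon choice is uniform over synonymous codons; padding is uniform
random ACGT with the left pad length adjusted so the left arm starts in
the requested reading frame.  All randomness flows through one seeded
``random.Random`` stream, so identical seeds give identical output bytes.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .engine import FORWARD, REVERSE
from .seqcore import AMINO_ACIDS, CODON_TO_AA, NucRecord, PepRecord, reverse_complement

__all__ = [
    "InfeasibleEventError",
    "PlantedEvent",
    "SYNONYMOUS_CODONS",
    "reverse_translate",
    "simulate_embedded_event",
    "generate_benchmark_set",
    "embed_decoys",
    "write_truth_table",
    "expected_direction",
    "event_matches_planted",
    "recall",
]

DEFAULT_CLASSES = (-2, -1, 0, 1, 2)

# amino acid -> sorted list of codons (standard code, stops excluded)
SYNONYMOUS_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        SYNONYMOUS_CODONS.setdefault(_aa, []).append(_codon)


class InfeasibleEventError(ValueError):
    """No synonymous codon combination satisfies the requested arm overlap."""


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one embedded event (one row of the truth table)."""

    peptide_id: str
    subject_id: str
    peptide: str
    split_k: Optional[int]  # None for the gap-0 (non-chimeric) class
    gap_class: int
    strand: str
    frame_left: int
    direction: Optional[tuple[int, int]]  # None for gap-0 plantings


def expected_direction(frame_left: int, gap: int) -> tuple[int, int]:
    """Frame pair implied by a left-arm frame and a gap (frame-consistency law)."""
    return frame_left, (frame_left - 1 + gap) % 3 + 1


def reverse_translate(pep: str, rng: random.Random) -> str:
    """Encode a peptide with uniformly chosen synonymous codons."""
    return "".join(rng.choice(SYNONYMOUS_CODONS[aa]) for aa in pep)


def _random_nt(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _codon_choices(pep: str, rng: random.Random) -> list[list[str]]:
    """Per-residue synonymous codon lists in a seeded random order."""
    return [rng.sample(SYNONYMOUS_CODONS[aa], len(SYNONYMOUS_CODONS[aa])) for aa in pep]


def _encode_with_prefix(pep: str, prefix: str, rng: random.Random) -> Optional[str]:
    """Nucleotide encoding of ``pep`` whose first ``len(prefix)`` nt equal
    ``prefix``, or None when no synonymous combination achieves it."""
    m = math.ceil(len(prefix) / 3)
    if m > len(pep):
        return None
    for combo in itertools.product(*_codon_choices(pep[:m], rng)):
        head = "".join(combo)
        if head.startswith(prefix):
            return head + reverse_translate(pep[m:], rng)
    return None


def _build_insert(peptide: str, split_k: Optional[int], gap: int, rng: random.Random) -> str:
    """The coding insert: left arm, gap/overlap, right arm."""
    if split_k is None or gap == 0:
        return reverse_translate(peptide, rng)
    s1, s2 = peptide[:split_k], peptide[split_k:]
    if gap > 0:
        return reverse_translate(s1, rng) + _random_nt(gap, rng) + reverse_translate(s2, rng)
    g = -gap
    if g > 3 * len(s1) or g > 3 * len(s2):
        raise InfeasibleEventError(
            f"overlap of {g} nt exceeds an arm's coding range "
            f"({len(s1)} aa / {len(s2)} aa)"
        )
    # last ceil(g/3) left codons constrain the overlap; try synonymous combos
    m = math.ceil(g / 3)
    left_head = reverse_translate(s1[:-m], rng)
    for tail_combo in itertools.product(*_codon_choices(s1[-m:], rng)):
        tail = "".join(tail_combo)
        overlap = tail[-g:]
        right_nt = _encode_with_prefix(s2, overlap, rng)
        if right_nt is not None:
            return left_head + tail + right_nt[g:]
    raise InfeasibleEventError(
        f"no synonymous codons give a {g} nt overlap between "
        f"...{s1[-m:]} and {s2[:math.ceil(g / 3)]}..."
    )


def simulate_embedded_event(
    peptide: str,
    split_k: Optional[int],
    gap: int,
    strand: str = FORWARD,
    frame_left: int = 1,
    padding: tuple[int, int] = (20, 120),
    rng: Optional[random.Random] = None,
    subject_id: str = "synthetic_subject",
    peptide_id: str = "planted_peptide",
) -> tuple[NucRecord, PlantedEvent]:
    """Embed one peptide event in a randomly padded synthetic subject.

    The returned subject is guaranteed to contain the planted event:
    the search engine recovers at least one event with exactly this
    (split_k, gap, strand) and the frame direction implied by
    ``frame_left``.  ``padding`` is the (min, max) random pad length per
    side; the left pad is then lengthened by 0-2 nt so the left arm
    starts in ``frame_left``.

    Raises :class:`InfeasibleEventError` when a negative-gap overlap is
    impossible for the boundary residues; callers resample.
    """
    if rng is None:
        rng = random.Random()
    if split_k is not None and gap != 0 and not 1 <= split_k <= len(peptide) - 1:
        raise ValueError("split_k must be between 1 and len(peptide) - 1")
    if frame_left not in (1, 2, 3):
        raise ValueError("frame_left must be 1, 2, or 3")

    insert = _build_insert(peptide, split_k, gap, rng)

    lpad_n = rng.randint(*padding)
    lpad_n += (frame_left - 1 - lpad_n) % 3
    rpad_n = rng.randint(*padding)
    searched = _random_nt(lpad_n, rng) + insert + _random_nt(rpad_n, rng)
    subject_seq = reverse_complement(searched) if strand == REVERSE else searched

    chimeric = split_k is not None and gap != 0
    truth = PlantedEvent(
        peptide_id=peptide_id,
        subject_id=subject_id,
        peptide=peptide,
        split_k=split_k if chimeric else None,
        gap_class=gap,
        strand=strand,
        frame_left=frame_left,
        direction=expected_direction(frame_left, gap) if chimeric else None,
    )
    return NucRecord(title=subject_id, seq=subject_seq), truth


def _random_peptide(length: int, rng: random.Random) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def generate_benchmark_set(
    n_per_class: int = 20,
    peptide_length_range: tuple[int, int] = (8, 30),
    seed: int = 0,
    classes: Sequence[int] = DEFAULT_CLASSES,
    padding: tuple[int, int] = (20, 120),
    max_attempts: int = 1000,
) -> tuple[list[PepRecord], list[NucRecord], list[PlantedEvent]]:
    """Simulated benchmark: ``n_per_class`` peptides per frameshift class.

    Each peptide is embedded in its own subject with a random split
    point, strand, and left-arm frame.  Infeasible negative-overlap
    draws are resampled (never silently dropped), so every class is
    fully represented.  Output is reproducible from the seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    lo, hi = peptide_length_range
    if not 2 <= lo <= hi <= 60:
        raise ValueError("peptide lengths must satisfy 2 <= min <= max <= 60")

    rng = random.Random(seed)
    peptides: list[PepRecord] = []
    subjects: list[NucRecord] = []
    truth: list[PlantedEvent] = []
    for cls in classes:
        tag = f"m{-cls}" if cls < 0 else (f"p{cls}" if cls > 0 else "z0")
        for i in range(1, n_per_class + 1):
            pep_id = f"pep_{tag}_{i:03d}"
            subj_id = f"subj_{tag}_{i:03d}"
            for _ in range(max_attempts):
                length = rng.randint(lo, hi)
                pep = _random_peptide(length, rng)
                split_k = rng.randint(1, length - 1) if cls != 0 else None
                strand = rng.choice((FORWARD, REVERSE))
                frame_left = rng.randint(1, 3)
                try:
                    subject, planted = simulate_embedded_event(
                        pep, split_k, cls,
                        strand=strand, frame_left=frame_left, padding=padding,
                        rng=rng, subject_id=subj_id, peptide_id=pep_id,
                    )
                except InfeasibleEventError:
                    continue
                break
            else:  # pragma: no cover - astronomically unlikely at these gaps
                raise InfeasibleEventError(
                    f"could not plant a class {cls} event in {max_attempts} attempts"
                )
            peptides.append(PepRecord(title=pep_id, seq=pep))
            subjects.append(subject)
            truth.append(planted)
    return peptides, subjects, truth


def embed_decoys(
    subjects: Sequence[NucRecord],
    decoy_count: int,
    seed: int = 0,
    length_range: tuple[int, int] = (200, 400),
) -> list[NucRecord]:
    """Append random nucleotide records containing no planted events.

    Decoys estimate the spurious-match background at a given gap
    setting; any hit on them is a chance match.
    """
    if decoy_count < 0:
        raise ValueError("decoy_count must be >= 0")
    rng = random.Random(seed)
    out = list(subjects)
    for i in range(1, decoy_count + 1):
        n = rng.randint(*length_range)
        out.append(NucRecord(title=f"decoy_{i:03d}", seq=_random_nt(n, rng)))
    return out


def event_matches_planted(event, planted: PlantedEvent) -> bool:
    """True when a search result matches a truth-table row exactly.

    Chimeric plantings must be recovered with the planted gap, split
    point, strand, and frame direction; gap-0 plantings as a
    "Without frameshift" source on the planted strand.
    """
    if event.protein_title != planted.peptide_id:
        return False
    if event.nucleotide_title.split()[0] != planted.subject_id:
        return False
    if planted.split_k is None:
        return event.type_label == "Without frameshift" and event.strand == planted.strand
    return (
        event.type_label == "Frameshift"
        and event.gap == planted.gap_class
        and event.frameshift_position == planted.split_k
        and event.strand == planted.strand
        and event.direction == planted.direction
    )


def recall(events: Sequence, truth: Sequence[PlantedEvent]) -> float:
    """Fraction of truth rows recovered by at least one search result."""
    hit = sum(
        any(event_matches_planted(e, t) for e in events) for t in truth
    )
    return hit / len(truth) if truth else 1.0


def write_truth_table(truth: Sequence[PlantedEvent], path) -> None:
    """Write planted parameters as TSV (schema documented in the README)."""
    cols = (
        "peptide_id", "subject_id", "peptide", "split_k",
        "gap", "strand", "frame_left", "direction",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            direction = f"{t.direction[0]}->{t.direction[1]}" if t.direction else ""
            fh.write(
                "\t".join(
                    (
                        t.peptide_id,
                        t.subject_id,
                        t.peptide,
                        "" if t.split_k is None else str(t.split_k),
                        f"+{t.gap_class}" if t.gap_class > 0 else str(t.gap_class),
                        t.strand,
                        str(t.frame_left),
                        direction,
                    )
                )
                + "\n"
            )
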