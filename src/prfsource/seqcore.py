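"""Nucleotide and peptide primitives: alphabets, reverse complement,
codon translation, and reading-frame arithmetic.

Everything here is a pure function or a plain record; FASTA I/O lives in
:mod:`prfsource.reportio`.

Frame convention
----------------
Reading frames are labelled 1, 2, 3 by the 0-based offset of the first
codon modulo 3, computed on the *searched* strand.  For reverse-strand
searches the searched strand is the reverse complement of the input
sequence with its own 0-based origin; the strand itself is reported
separately, so frame labels are always in {1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

__all__ = [
    "AlphabetError",
    "NucRecord",
    "PepRecord",
    "normalize_nuc",
    "normalize_pep",
    "reverse_complement",
    "translate",
    "frame_of_offset",
    "AMINO_ACIDS",
    "NUC_ALPHABET",
]


class AlphabetError(ValueError):
    """A sequence contains a character outside its allowed alphabet."""


NUC_ALPHABET = frozenset("ACGTN")

# The 20 standard amino acids; ambiguity codes (B, J, Z, X), stops and
# non-standard residues are rejected in queries because an arm containing
# them can never be matched exactly.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (translation table 1).
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE.stop_codons})


def normalize_nuc(seq: str, unknown_to_n: bool = False) -> str:
    """Normalize a raw nucleotide string to uppercase {A,C,G,T,N}.

    Lowercase input is accepted; ``U`` is mapped to ``T`` so RNA FASTA
    files are tolerated.  Any other character raises
    :class:`AlphabetError` (naming the 1-based position and the
    character) unless ``unknown_to_n`` is set, in which case it is
    mapped to ``N``.
    """
    out = seq.upper().replace("U", "T")
    bad = [i for i, c in enumerate(out) if c not in NUC_ALPHABET]
    if bad:
        if unknown_to_n:
            chars = list(out)
            for i in bad:
                chars[i] = "N"
            return "".join(chars)
        i = bad[0]
        raise AlphabetError(
            f"invalid nucleotide {out[i]!r} at position {i + 1}"
        )
    return out


def normalize_pep(seq: str) -> str:
    """Normalize a raw peptide string to the 20 uppercase standard residues.

    Stops ('*') and ambiguity codes (B, J, Z, X, and anything else
    non-standard) raise :class:`AlphabetError` with the offending
    1-based position.
    """
    out = seq.upper()
    for i, c in enumerate(out):
        if c not in _AA_SET:
            raise AlphabetError(
                f"invalid amino acid {c!r} at position {i + 1}"
            )
    return out


@dataclass(frozen=True)
class NucRecord:
    """One subject nucleotide sequence (FASTA header + sequence).

    ``title`` is the full header line after '>'; its first token is the
    locus ID and the remainder free-text annotation.  ``seq`` is
    normalized uppercase {A,C,G,T,N}.
    """

    title: str
    seq: str

    @classmethod
    def from_raw(cls, title: str, raw_seq: str, unknown_to_n: bool = False) -> "NucRecord":
        return cls(title=title, seq=normalize_nuc(raw_seq, unknown_to_n))

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PepRecord:
    """One query peptide (FASTA header + amino acid sequence)."""

    title: str
    seq: str

    @classmethod
    def from_raw(cls, title: str, raw_seq: str) -> "PepRecord":
        return cls(title=title, seq=normalize_pep(raw_seq))

    @property
    def length(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N.

    Involution: applying twice returns the input.
    """
    for i, c in enumerate(seq):
        if c not in NUC_ALPHABET:
            raise AlphabetError(f"invalid nucleotide {c!r} at position {i + 1}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, offset: int = 0) -> str:
    """Translate successive codons of ``seq`` starting at ``offset``.

    Translation stops when fewer than 3 nt remain.  Stop codons emit
    '*'.  Any codon containing N emits 'X' — an X can never match a
    query arm, so ambiguous regions silently produce no matches.
    """
    if not 0 <= offset <= len(seq):
        raise IndexError(
            f"offset {offset} out of range for sequence of length {len(seq)}"
        )
    aa = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


def frame_of_offset(offset: int) -> int:
    """Reading-frame label in {1,2,3} of a 0-based nucleotide offset."""
    return offset % 3 + 1
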