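"""Independent brute-force oracle for the arm-pairing search.

Deliberately avoids the package's translation and frame machinery:
codons are translated one at a time through Bio.Seq, and every
(split, left start, right start) triple is checked directly against the
nucleotide sequence.  Only suitable for small instances.
"""

from functools import lru_cache

from Bio.Seq import Seq


@lru_cache(maxsize=None)
def _codon_aa(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def encodes_at(seq: str, pos: int, pep: str) -> bool:
    """Does translation starting at ``pos`` begin with ``pep``?"""
    if pos < 0 or pos + 3 * len(pep) > len(seq):
        return False
    for i, aa in enumerate(pep):
        if _codon_aa(seq[pos + 3 * i : pos + 3 * i + 3]) != aa:
            return False
    return True


def oracle_search(queries, subjects, max_gap, search_reverse=True):
    """All sources as comparable tuples:

    (query_idx, subject_idx, strand, kind, left_start, gap, split, direction)
    with kind "NC" for contiguous matches and "FS" for frameshift events.
    """
    found = set()
    for qi, q in enumerate(queries):
        pep = q.seq
        for si, s in enumerate(subjects):
            strands = [("forward", s.seq)]
            if search_reverse:
                strands.append(("reverse", str(Seq(s.seq).reverse_complement())))
            for strand, seq in strands:
                n = len(seq)
                for pos in range(n):
                    if encodes_at(seq, pos, pep):
                        found.add((qi, si, strand, "NC", pos, 0, None, None))
                for k in range(1, len(pep)):
                    s1, s2 = pep[:k], pep[k:]
                    lefts = [i for i in range(n) if encodes_at(seq, i, s1)]
                    if not lefts:
                        continue
                    rights = [i for i in range(n) if encodes_at(seq, i, s2)]
                    for left in lefts:
                        end = left + 3 * k
                        for right in rights:
                            gap = right - end
                            if gap != 0 and abs(gap) <= max_gap:
                                found.add(
                                    (
                                        qi, si, strand, "FS", left, gap, k,
                                        (left % 3 + 1, right % 3 + 1),
                                    )
                                )
    return found


def events_as_tuples(events):
    """Engine results in the oracle's tuple form."""
    out = set()
    for e in events:
        if e.type_label == "Frameshift":
            out.add(
                (
                    e.query_index, e.subject_index, e.strand, "FS",
                    e.left_nt_start, e.gap, e.frameshift_position, e.direction,
                )
            )
        else:
            out.add(
                (e.query_index, e.subject_index, e.strand, "NC",
                 e.left_nt_start, 0, None, None)
            )
    return out
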