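import random

import pytest

from prfsource import (
    FORWARD,
    REVERSE,
    NucRecord,
    PepRecord,
    RunConfig,
    enumerate_splits,
    find_nonchimeric,
    find_occurrences,
    pair_occurrences,
    search,
    simulate_embedded_event,
)
from prfsource.engine import ContractError, NothingToSearchError, SegmentOccurrence

from conftest import make_nuc, make_pep


class TestEnumerateSplits:
    def test_split_count_and_order(self):
        splits = enumerate_splits(make_pep("ILDTHIHR"))
        assert len(splits) == 8  # 7 two-arm splits + 1 full-length entry
        assert splits[0] == ("I", "LDTHIHR")
        assert splits[-1] == ("ILDTHIHR", "")
        assert [len(a) for a, _ in splits[:-1]] == list(range(1, 8))

    def test_known_arm_boundary(self):
        splits = enumerate_splits(make_pep("RCLGVGARR"))
        assert splits[2] == ("RCL", "GVGARR")

    def test_minimal_peptide(self):
        assert enumerate_splits(make_pep("MK")) == [("M", "K"), ("MK", "")]


class TestFindOccurrences:
    def test_direct_encoding_frame1(self):
        occs = find_occurrences("MA", make_nuc("ATGGCTTAA"), FORWARD)
        assert [(o.nt_start, o.frame) for o in occs] == [(0, 1)]
        assert occs[0].nt_end == 6

    def test_frame2_occurrence(self):
        occs = find_occurrences("MA", make_nuc("GATGGCTTAA"), FORWARD)
        assert [(o.nt_start, o.frame) for o in occs] == [(1, 2)]

    def test_reverse_strand_coordinates(self):
        # reverse complement of ATGATGATG is CATCATCAT; CAT = His
        occs = find_occurrences("H", make_nuc("ATGATGATG"), REVERSE)
        assert [o.nt_start for o in occs] == [0, 3, 6]
        assert all(o.strand == REVERSE for o in occs)

    def test_absent_arm_gives_empty_list(self):
        assert find_occurrences("W", make_nuc("AAAAAA"), FORWARD) == []

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            find_occurrences("", make_nuc("ATG"), FORWARD)


def _occ(start, arm, strand=FORWARD, subject_index=0):
    return SegmentOccurrence(
        subject_index=subject_index,
        strand=strand,
        nt_start=start,
        nt_end=start + 3 * len(arm),
        aa_seq=arm,
    )


class TestPairOccurrences:
    CFG = RunConfig(max_gap=2)
    Q = make_pep("MK")
    S = make_nuc("A" * 30)

    def pair(self, left, right, cfg=CFG):
        return pair_occurrences(left, right, cfg, query=self.Q, subject=self.S)

    def test_positive_gap_reported_as_plus(self):
        ev = self.pair(_occ(0, "M"), _occ(5, "K"))
        assert ev is not None and ev.gap == 2
        assert ev.direction == (1, 3)

    def test_negative_gap_reported_as_minus(self):
        ev = self.pair(_occ(0, "M"), _occ(1, "K"))
        assert ev is not None and ev.gap == -2
        assert ev.frameshift_position == 1

    def test_gap_zero_never_a_frameshift(self):
        assert self.pair(_occ(0, "M"), _occ(3, "K")) is None

    def test_gap_outside_window_rejected(self):
        assert self.pair(_occ(0, "M"), _occ(6, "K")) is None
        assert self.pair(_occ(6, "M"), _occ(0, "K")) is None

    def test_mismatched_strand_is_contract_violation(self):
        with pytest.raises(ContractError):
            self.pair(_occ(0, "M"), _occ(5, "K", strand=REVERSE))


def test_worked_plus2_event_from_literal_fixture():
    """A +2 event built by hand: left arm RCL in frame 2, right arm GVGARR
    in frame 1, spaced by 2 nt, splits RCLGVGARR at position 3 with
    direction 2->1."""
    subject = make_nuc("G" + "CGTTGTCTT" + "AA" + "GGTGTTGGTGCTCGTCGT")
    events = search([make_pep("RCLGVGARR", "CP60")], [subject], RunConfig(max_gap=2))
    chimeric = [e for e in events if e.type_label == "Frameshift"]
    assert any(
        e.gap == 2 and e.direction == (2, 1) and e.frameshift_position == 3
        and e.segment1 == "RCL" and e.segment2 == "GVGARR"
        for e in chimeric
    )


class TestFindNonchimeric:
    def test_forward_contiguous_match(self):
        evs = find_nonchimeric(make_pep("MA"), make_nuc("ATGGCT"), FORWARD)
        assert len(evs) == 1
        e = evs[0]
        assert e.type_label == "Without frameshift"
        assert e.gap == 0 and e.segment2 == "" and e.direction is None
        assert e.frameshift_position is None

    def test_reverse_contiguous_match(self):
        evs = find_nonchimeric(make_pep("MA"), make_nuc("AGCCAT"), REVERSE)
        assert len(evs) == 1
        assert evs[0].frame_direction == "Reverse Frame"

    def test_no_contiguous_encoding(self):
        assert find_nonchimeric(make_pep("MA"), make_nuc("ATGAGCT"), FORWARD) == []


class TestSearch:
    def test_empty_inputs_rejected(self):
        with pytest.raises(NothingToSearchError):
            search([], [make_nuc("ATG")])
        with pytest.raises(NothingToSearchError):
            search([make_pep("M")], [])

    def test_contiguous_match_collapses_to_one_record(self):
        """A full-length match must appear once as "Without frameshift",
        not as L-1 duplicate gap-0 split derivations."""
        # MKWV encoded contiguously
        subject = make_nuc("CCC" + "ATGAAATGGGTT" + "CCC")
        events = search([make_pep("MKWV")], [subject], RunConfig(max_gap=2))
        nc = [e for e in events if e.type_label == "Without frameshift"]
        assert len(nc) == 1
        assert all(e.gap != 0 for e in events if e.type_label == "Frameshift")

    def test_no_shared_arm_gives_empty_result(self):
        events = search([make_pep("WW")], [make_nuc("AAAAAAAAA")], RunConfig())
        assert events == []

    def test_figure_scenario_minus2_with_8aa_left_arm(self, rng):
        from prfsource import InfeasibleEventError

        while True:
            pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(10))
            try:
                subject, truth = simulate_embedded_event(
                    pep, 8, -2, strand=FORWARD, frame_left=1, rng=rng, subject_id="locus"
                )
            except InfeasibleEventError:
                continue
            break
        events = search([PepRecord("p10", pep)], [subject], RunConfig(max_gap=2))
        hits = [
            e for e in events
            if e.type_label == "Frameshift" and e.gap == -2 and e.frameshift_position == 8
        ]
        assert hits, "planted -2 event with an 8 aa left arm not recovered"
        assert len(hits[0].segment1) == 8 and len(hits[0].segment2) == 2

    def test_monotonic_in_max_gap(self, rng):
        peps, subs, _ = _small_instance(rng)
        for g in (1, 2, 3):
            smaller = _keys(search(peps, subs, RunConfig(max_gap=g)))
            larger = _keys(search(peps, subs, RunConfig(max_gap=g + 1)))
            assert smaller <= larger

    def test_strand_symmetry_bijection(self, rng):
        """Reverse-strand events against S are the forward-strand events
        against reverse_complement(S), with strand labels swapped."""
        from prfsource import reverse_complement

        peps, subs, _ = _small_instance(rng)
        flipped = [NucRecord(s.title, reverse_complement(s.seq)) for s in subs]
        direct = _keys(search(peps, subs, RunConfig(max_gap=2)))
        mirrored = _keys(search(peps, flipped, RunConfig(max_gap=2)))
        # reverse-strand coordinates live on the reverse complement, so the
        # bijection is exact key equality once strand labels are swapped
        swapped = {
            (q, s, FORWARD if st == REVERSE else REVERSE, left, gap, pos)
            for (q, s, st, left, gap, pos) in mirrored
        }
        assert direct == swapped

    def test_thread_invariance(self, rng):
        peps, subs, _ = _small_instance(rng, n=6)
        one = search(peps, subs, RunConfig(max_gap=2, threads=1))
        eight = search(peps, subs, RunConfig(max_gap=2, threads=8))
        assert one == eight

    def test_repeatability(self, rng):
        peps, subs, _ = _small_instance(rng)
        assert search(peps, subs) == search(peps, subs)


def _small_instance(rng, n=4):
    """A few planted events plus their peptides, for search-level properties."""
    import prfsource.simulate as sim

    peps, subs, truth = [], [], []
    classes = [-2, -1, 0, 1, 2]
    for i in range(n):
        cls = classes[i % len(classes)]
        length = rng.randint(6, 12)
        while True:
            pep = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
            split = rng.randint(1, length - 1) if cls != 0 else None
            try:
                sub, t = sim.simulate_embedded_event(
                    pep, split, cls,
                    strand=rng.choice((FORWARD, REVERSE)),
                    frame_left=rng.randint(1, 3),
                    padding=(10, 40), rng=rng,
                    subject_id=f"s{i}", peptide_id=f"p{i}",
                )
            except sim.InfeasibleEventError:
                continue
            break
        peps.append(PepRecord(f"p{i}", pep))
        subs.append(sub)
        truth.append(t)
    return peps, subs, truth


def _keys(events):
    return {
        (e.query_index, e.subject_index, e.strand, e.left_nt_start,
         e.gap, e.frameshift_position)
        for e in events
    }


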