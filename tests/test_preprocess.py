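"""Trimming, filtering, and the ungapped one-mismatch aligner."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isomirseq.preprocess import (ArmAlignment, TrimmedRead, align_sample,
                                  align_ungapped, assign_to_arm,
                                  collapse_and_filter, resolve_candidates,
                                  trim_adapter)
from isomirseq.reference import HairpinReference

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAdapter:
    def test_exact_prefix_removal(self):
        assert trim_adapter("ACGTACGT" + ADAPTER[:8], ADAPTER) == ("ACGTACGT", True)

    def test_full_read_without_adapter_flagged(self):
        seq = "ACGTACGTACGTACGTAAC"
        assert trim_adapter(seq, ADAPTER) == (seq, False)

    def test_adapter_at_position_zero_gives_empty_insert(self):
        assert trim_adapter(ADAPTER + "AAA", ADAPTER) == ("", True)

    def test_full_adapter_with_ten_percent_mismatches(self):
        mutated = "A" + ADAPTER[1:-1] + "C"  # 2 mismatches in 21 nt -> 9.5%
        assert trim_adapter("CCCC" + mutated, ADAPTER) == ("CCCC", True)

    def test_short_overlap_below_minimum_not_trimmed(self):
        seq = "ACGTACGTACGTACGT" + ADAPTER[:2]
        assert trim_adapter(seq, ADAPTER, min_overlap=3) == (seq, False)

    def test_full_adapter_occurrence_beats_later_partial(self):
        insert = "CCCC"
        mutated = "A" + ADAPTER[1:]  # full-length, 1 mismatch
        read = insert + mutated + "AC"
        assert trim_adapter(read, ADAPTER)[0] == insert


class TestCollapseAndFilter:
    def test_identical_reads_merged(self):
        reads = ["ACGTACGTACGTACGTACGTAC"] * 3
        collapsed, tally = collapse_and_filter(reads)
        assert len(collapsed) == 1 and collapsed[0].count == 3

    def test_length_bounds(self):
        collapsed, tally = collapse_and_filter(
            ["ACGTACGTAC", "A" * 30, "ACGTACGTACGTACGTACGTAC"])
        assert tally.too_short == 1 and tally.too_long == 1
        assert len(collapsed) == 1

    def test_quality_filter(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        collapsed, tally = collapse_and_filter(
            [(seq, "I" * len(seq)), (seq, "#" * len(seq))])
        assert tally.low_quality == 1 and collapsed[0].count == 1

    def test_count_conservation(self):
        reads = ["ACGT" * 5, "A" * 5, "C" * 40, "ACGT" * 5, "TTTTACGTACGTACGTTTTT"]
        _, tally = collapse_and_filter(reads)
        assert tally.conserved()
        assert tally.input == len(reads)


def _brute_force_align(read, hairpins, max_mismatch=1, min_templated=15):
    """Independent exhaustive sliding-window search (test oracle)."""
    hits = []
    for hid in sorted(hairpins):
        ref = hairpins[hid].extended
        for pos in range(len(hairpins[hid].sequence)):
            limit = min(len(read), len(ref) - pos)
            valid = []
            for L in range(min_templated, limit + 1):
                mm = sum(a != b for a, b in zip(read[:L], ref[pos:pos + L]))
                if mm <= max_mismatch and read[L - 1] == ref[pos + L - 1]:
                    valid.append((mm, len(read) - L, L))
            if valid:
                mm, tail_len, L = min(valid)
                hits.append((mm, tail_len, hid, pos + 1, L))
    hits.sort()
    return hits


class TestAlignUngapped:
    def test_interior_substring_single_hit(self, hairpins):
        hp = hairpins["syn-mir-1"]
        read = TrimmedRead(hp.sequence[5:27])
        cands = align_ungapped(read, {"syn-mir-1": hp})
        assert cands[0].mismatches == 0 and cands[0].tail == ""
        assert cands[0].start_pos == 6

    def test_internal_substitution_counted(self, hairpins):
        hp = hairpins["syn-mir-1"]
        seq = list(hp.sequence[5:27])
        seq[10] = "A" if seq[10] != "A" else "C"
        cands = align_ungapped(TrimmedRead("".join(seq)), {"syn-mir-1": hp})
        best = cands[0]
        assert best.mismatches == 1 and best.start_pos == 6 and best.tail == ""

    def test_terminal_mismatch_becomes_tail_not_mismatch(self, hairpins):
        hp = hairpins["syn-mir-1"]
        body = hp.sequence[5:26]
        bad = "T" if hp.sequence[26] != "T" else "G"
        cands = align_ungapped(TrimmedRead(body + bad), {"syn-mir-1": hp})
        best = cands[0]
        assert best.mismatches == 0 and best.tail == bad

    def test_read_on_two_hairpins_is_ambiguous(self):
        core = "ACGTTGCAACGGTCAGGTCCAG"
        h1 = HairpinReference("h1", "AAAAA" + core + "GGGGG" + "C" * 20,
                              flank3="A" * 10)
        h2 = HairpinReference("h2", "TTTTT" + core + "CCCCC" + "G" * 20,
                              flank3="A" * 10)
        cands = align_ungapped(TrimmedRead(core), {"h1": h1, "h2": h2})
        best = resolve_candidates(cands)
        assert best.ambiguous

    def test_no_indel_representable(self, hairpins):
        read = TrimmedRead("ACGTACGTACGTACGTACGTAC")
        with pytest.raises(ValueError):
            ArmAlignment(read, "h", 1, 10, 0, "x")  # lengths do not add up
        with pytest.raises(ValueError):
            ArmAlignment(read, "h", 1, len(read.sequence), 2, "")

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        """Aligner output equals an exhaustive sliding-window search on
        random references and reads with planted substitutions."""
        rng = np.random.default_rng(seed)
        hairpins = {}
        for i in range(rng.integers(1, 6)):
            body = "".join(rng.choice(list("ACGT"), size=60))
            flank = "".join(rng.choice(list("ACGT"), size=10))
            hairpins[f"h{i}"] = HairpinReference(f"h{i}", body, flank3=flank)
        hp = hairpins[f"h{rng.integers(0, len(hairpins))}"]
        start = int(rng.integers(0, 38))
        read = list(hp.sequence[start:start + 22])
        if rng.random() < 0.7:   # plant an internal substitution
            j = int(rng.integers(1, len(read) - 1))
            read[j] = rng.choice([b for b in "ACGT" if b != read[j]])
        read = "".join(read)

        cands = align_ungapped(TrimmedRead(read), hairpins)
        oracle = _brute_force_align(read, hairpins)
        got = sorted((c.mismatches, len(c.tail), c.hairpin_id, c.start_pos,
                      c.templated_len) for c in cands)
        assert got == sorted(oracle)


class TestAssignToArm:
    def test_exact_arm_start_gives_offset_zero(self, hairpins, arms):
        hp = hairpins["syn-mir-1"]
        read = TrimmedRead(hp.sequence[5:27])
        best = align_ungapped(read, {"syn-mir-1": hp})[0]
        placed = assign_to_arm(best, list(arms.values()))
        assert placed.arm.name == "syn-miR-1-5p"
        assert placed.start_pos - placed.arm.arm_start == 0

    def test_read_near_3p_arm_assigned_to_3p(self, hairpins, arms):
        hp = hairpins["syn-mir-1"]
        read = TrimmedRead(hp.sequence[45:67])
        best = align_ungapped(read, {"syn-mir-1": hp})[0]
        placed = assign_to_arm(best, list(arms.values()))
        assert placed.arm.name == "syn-miR-1-3p"

    def test_loop_read_far_from_both_arms_unassigned(self, hairpins, arms):
        hp = hairpins["syn-mir-1"]
        read = TrimmedRead(hp.sequence[25:47])  # starts 20 right of 5p,
        best = align_ungapped(read, {"syn-mir-1": hp})[0]  # 20 left of 3p
        assert assign_to_arm(best, list(arms.values()), cap_5p=4) is None


def test_count_conservation_through_alignment(hairpins, arms):
    """input = unaligned + ambiguous + unassigned + assigned, per sample."""
    hp = hairpins["syn-mir-1"]
    reads = [
        TrimmedRead(hp.sequence[5:27], count=7),          # assigned
        TrimmedRead("ACGTACGTACGTACGTACGTAC", count=3),   # unaligned
        TrimmedRead(hp.sequence[25:47], count=2),         # unassigned (loop)
    ]
    aligned, tally = align_sample(reads, hairpins, arms)
    assert tally.conserved()
    assert tally.input == 12 and tally.assigned == 7
    assert sum(a.read.count for a in aligned) == 7
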