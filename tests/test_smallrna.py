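"""Read cleaning, tag collapsing, composition statistics and known-miRNA
assignment."""

import io

import pytest
from conftest import random_rna

from shademir.smallrna import (
    FastqParseError,
    MirnaRecord,
    SequenceTag,
    clean_reads,
    collapse_libraries,
    composition_stats,
    match_known,
    tags_to_frame,
)


def fastq_text(reads):
    """reads: list of (seq, qual_char) or (seq, qual_string)."""
    chunks = []
    for i, (seq, qual) in enumerate(reads):
        q = qual * len(seq) if len(qual) == 1 else qual
        chunks.append(f"@r{i}\n{seq}\n+\n{q}\n")
    return io.StringIO("".join(chunks))


Q40 = "I"  # phred 40
Q20 = "5"  # phred 20


class TestCleanReads:
    def test_empty_input_gives_empty_tag_list(self):
        assert clean_reads(fastq_text([])) == []

    def test_identical_reads_collapse_to_one_tag(self):
        reads = [("ACGTACGTACGTACGTACGTA", Q40)] * 4
        tags = clean_reads(fastq_text(reads), library="L1")
        assert len(tags) == 1
        assert tags[0].sequence == "ACGUACGUACGUACGUACGUA"  # T -> U
        assert tags[0].counts == {"L1": 4}

    def test_length_filter_drops_short_reads(self, rng):
        short = [(random_rna(rng, 15).replace("U", "T"), Q40) for _ in range(3)]
        ok = [(random_rna(rng, 21).replace("U", "T"), Q40) for _ in range(7)]
        tags = clean_reads(fastq_text(short + ok))
        assert sum(t.total_count for t in tags) == 7
        assert all(17 <= t.length <= 25 for t in tags)

    def test_low_quality_base_drops_whole_read(self):
        seq = "ACGTACGTACGTACGTACGTA"
        reads = [(seq, Q40), (seq, Q40[0] * 10 + Q20 + Q40[0] * 10)]
        tags = clean_reads(fastq_text(reads))
        assert sum(t.total_count for t in tags) == 1

    def test_adapter_clipped_before_filters(self):
        insert = "ACGTACGTACGTACGTACGTA"
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        reads = [(insert + adapter, Q40)]
        tags = clean_reads(fastq_text(reads), adapter=adapter)
        assert [t.sequence for t in tags] == [insert.replace("T", "U")]

    def test_blacklisted_tags_removed_by_containment(self):
        seq = "ACGUACGUACGUACGUACGUA"
        rrna = "GGG" + seq + "CCC"  # tag fully contained in an rRNA
        tags = clean_reads(
            fastq_text([(seq.replace("U", "T"), Q40)]), blacklist=[rrna]
        )
        assert tags == []

    def test_malformed_record_names_index(self):
        bad = io.StringIO("@r0\nACGT\n+\nIIII\n@r1\nACGTACGT\n+\nIII\n")
        with pytest.raises(FastqParseError, match="index 1"):
            clean_reads(bad)

    def test_collapsing_conserves_total_retained_count(self, rng):
        reads = []
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(17, 26))).replace("U", "T")
            reads.extend([(seq, Q40)] * int(rng.integers(1, 4)))
        tags = clean_reads(fastq_text(reads))
        assert sum(t.total_count for t in tags) == len(reads)

    def test_multi_library_collapse_merges_counts(self):
        seq = "ACGTACGTACGTACGTACGTA"
        libs = {
            "sun_1": fastq_text([(seq, Q40)] * 2),
            "shade_1": fastq_text([(seq, Q40)] * 5),
        }
        tags = collapse_libraries(libs)
        assert len(tags) == 1
        assert tags[0].counts == {"sun_1": 2, "shade_1": 5}
        frame = tags_to_frame(tags)
        assert list(frame.columns) == ["sequence", "length", "count_shade_1", "count_sun_1"]


class TestCompositionStats:
    def test_single_tag(self):
        rep = composition_stats([SequenceTag("ACGU", {"l": 1})])
        assert rep.length_percent[4] == 100.0
        assert rep.first_nt_percent.loc[4, "A"] == 100.0

    def test_unweighted_symmetry(self):
        tags = [SequenceTag("AAAA", {"l": 10}), SequenceTag("CCCC", {"l": 1})]
        rep = composition_stats(tags, weighted=False)
        assert rep.first_nt_percent.loc[4, "A"] == 50.0
        assert rep.first_nt_percent.loc[4, "C"] == 50.0

    def test_uniform_random_tags_near_25_percent_per_base(self, rng):
        tags = [SequenceTag(random_rna(rng, 21), {"l": 1}) for _ in range(100)]
        rep = composition_stats(tags)
        # recompute directly from the generated set
        from collections import Counter

        counts = Counter(b for t in tags for b in t.sequence)
        for base in "ACGU":
            expected = 100.0 * counts[base] / (100 * 21)
            assert rep.base_percent[base] == pytest.approx(expected)
            assert abs(rep.base_percent[base] - 25.0) < 5.0

    def test_percentages_sum_to_100(self, rng):
        tags = [
            SequenceTag(random_rna(rng, int(rng.integers(17, 26))), {"l": int(rng.integers(1, 9))})
            for _ in range(40)
        ]
        rep = composition_stats(tags)
        assert rep.length_percent.sum() == pytest.approx(100.0, abs=1e-9)
        for _, row in rep.first_nt_percent.iterrows():
            assert row.sum() == pytest.approx(100.0, abs=1e-9)
        assert rep.base_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance_under_count_multiplication(self, rng):
        tags = [
            SequenceTag(random_rna(rng, 21), {"l": int(rng.integers(1, 30))})
            for _ in range(30)
        ]
        scaled = [SequenceTag(t.sequence, {"l": t.counts["l"] * 7}) for t in tags]
        a, b = composition_stats(tags), composition_stats(scaled)
        assert a.length_percent.equals(b.length_percent)
        assert a.base_percent.equals(b.base_percent)

    def test_empty_input_defined(self):
        rep = composition_stats([])
        assert rep.length_percent.empty
        assert (rep.base_percent == 0).all()


class TestMatchKnown:
    REF = [
        MirnaRecord("osa-miR-b", "UGCCAAAGGAGAAUUGCCCUG"),
        MirnaRecord("osa-miR-a", "UGCCAAAGGAGAAUUGCCCUG"[:20] + "A"),
    ]

    def test_exact_match_assigned_zero_mismatches(self):
        tag = SequenceTag("UGCCAAAGGAGAAUUGCCCUG", {"l": 3})
        assign, counts = match_known([tag], [self.REF[0]])
        assert assign == {tag.sequence: "osa-miR-b"}
        assert counts.loc["osa-miR-b", "l"] == 3

    def test_three_mismatches_unassigned(self):
        seq = "AACCAAAGGAGAAUUGCCCAG"  # 3 substitutions
        assign, counts = match_known(
            [SequenceTag(seq, {"l": 1})], [self.REF[0]], max_mismatch=2
        )
        assert assign == {}
        assert counts.to_numpy().sum() == 0

    def test_tie_broken_lexicographically(self):
        # equal mismatch count against both references -> id "osa-miR-a"
        tag = SequenceTag("UGCCAAAGGAGAAUUGCCCUG"[:20] + "C", {"l": 1})
        assign, _ = match_known([tag], self.REF)
        assert assign[tag.sequence] == "osa-miR-a"

    def test_duplicate_reference_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            match_known([], [self.REF[0], self.REF[0]])

    def test_matches_brute_force_over_planted_mismatches(self, rng):
        refs = [MirnaRecord(f"m{i}", random_rna(rng, 21)) for i in range(2)]
        tags = []
        for i in range(5):
            base = list(refs[i % 2].mature_sequence)
            for _ in range(i % 3):  # 0-2 mismatches
                pos = int(rng.integers(0, 21))
                base[pos] = "A" if base[pos] != "A" else "C"
            tags.append(SequenceTag("".join(base), {"l": 1}))
        assign, _ = match_known(tags, refs, max_mismatch=2)
        # exhaustive oracle over all tag x reference comparisons
        for tag in tags:
            cands = []
            for r in refs:
                mm = sum(
                    1
                    for a, b in zip(tag.sequence, r.mature_sequence)
                    if a != b
                )
                if mm <= 2:
                    cands.append((mm, r.id))
            if cands:
                assert assign[tag.sequence] == min(cands)[1]
            else:
                assert tag.sequence not in assign

    def test_idempotent_and_order_invariant(self, rng):
        refs = [MirnaRecord(f"m{i}", random_rna(rng, 21)) for i in range(3)]
        tags = [SequenceTag(r.mature_sequence, {"l": i + 1}) for i, r in enumerate(refs)]
        a1, c1 = match_known(tags, refs)
        a2, c2 = match_known(list(reversed(tags)), refs)
        assert a1 == a2
        assert c1.equals(c2)
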