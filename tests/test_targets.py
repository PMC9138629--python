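"""Duplex penalty scoring, alignment and transcriptome scanning."""

import numpy as np
import pytest
from conftest import random_rna
from oracles import brute_force_best_alignment, naive_allen_recount

from shademir.rnautil import reverse_complement
from shademir.targets import (
    AllenParams,
    AlignmentError,
    align_duplex,
    allen_score,
    duplex_energies,
    extract_query,
    gapless_scores,
    scan_targets,
)

# the printed miR414 / potassium-antiporter duplex; miRNA strand reversed to
# the 3'->5' column convention
MIR414_SITE = "UCCUCCUCGUCCUCGUCGUU"
MIR414_MIR_3TO5 = "GACGAUGAUGACGAGGAUGA"[::-1]


class TestAllenScore:
    def test_printed_mir414_duplex_scores_4_5(self):
        assert allen_score(MIR414_SITE, MIR414_MIR_3TO5) == 4.5

    def test_perfect_watson_crick_duplex_scores_zero(self):
        mir = "UGCCAAAGGAGAAUUGCCCUG"
        site = reverse_complement(mir)
        assert allen_score(site, mir[::-1]) == 0.0

    def test_single_wobble_at_position_one_not_doubled(self):
        # miR 5' nucleotide sits at the right-hand end of the 3'->5' string
        mir = "GAAAAAAA"[::-1]
        site = "UUUUUUUU"  # G:U at position 1, rest A:U WC
        assert allen_score(site, mir) == 0.5

    def test_core_positions_doubled(self):
        mir = "AAAAAAAAAAAAAAA"  # 15 nt, all A (3'->5' string)
        site = "U" * 15
        # mismatch at miR position 5 (= column 11 of 15, counting from right)
        site = site[:10] + "C" + site[11:]
        assert allen_score(site, mir) == 2.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            allen_score("ACGU", "ACG")

    def test_matches_naive_recount_on_random_gapped_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(15, 25))
            site = list(random_rna(rng, n))
            mir = list(random_rna(rng, n))
            for _ in range(int(rng.integers(0, 3))):
                col = int(rng.integers(0, n))
                which = int(rng.integers(0, 2))
                (site if which else mir)[col] = "-"
            # avoid all-gap columns
            pairs = [
                (s, m) for s, m in zip(site, mir) if not (s == "-" and m == "-")
            ]
            s = "".join(p[0] for p in pairs)
            m = "".join(p[1] for p in pairs)
            assert allen_score(s, m) == naive_allen_recount(s, m)


class TestAlignDuplex:
    def test_perfect_complement_aligns_gapless_with_score_zero(self):
        mir = "UGCCAAAGGAGAAUUGCCCUG"
        aln = align_duplex(mir, reverse_complement(mir))
        assert aln.allen_score == 0.0
        assert "-" not in aln.site_aligned and "-" not in aln.mir_aligned
        assert set(aln.structure.replace("&", "")) == {"(", ")"}
        assert aln.expected_cs == aln.t_stop - 9

    def test_printed_mir399b_site_alignment_is_co_optimal(self):
        # the printed OsPP2C duplex has one site-side gap; the DP must find
        # an alignment of the same penalty with the same gap budget
        mir = "UGCCAAAGGAGAAUUGCCCUG"
        printed_site = "CGGGGGAGUUCUCGA-UGGCG"
        printed_score = allen_score(printed_site, mir[::-1])
        aln = align_duplex(mir, printed_site.replace("-", ""))
        assert aln.allen_score == printed_score == 8.5
        assert aln.site_aligned.count("-") == 1
        assert aln.mir_aligned.count("-") == 0

    def test_length_preconditions_enforced(self):
        with pytest.raises(AlignmentError):
            align_duplex("ACGUACGUACGU", "ACGUACGUACGU")  # miR too short
        with pytest.raises(AlignmentError):
            align_duplex("A" * 21, "A" * 26)  # site too long vs miR

    def test_dp_equals_exhaustive_enumeration_on_short_cases(self, rng):
        for _ in range(60):
            L = int(rng.integers(4, 8))
            S = max(3, L + int(rng.integers(-2, 3)))
            mir = random_rna(rng, L)
            site = random_rna(rng, S)
            aln = align_duplex(mir, site, enforce_bounds=False)
            assert aln.allen_score == brute_force_best_alignment(mir, site)
            # the emitted strings must re-score to the reported penalty
            assert naive_allen_recount(aln.site_aligned, aln.mir_aligned) == aln.allen_score

    def test_score_symmetric_under_joint_reversal_without_core_doubling(self, rng):
        flat = AllenParams(core_multiplier=1.0)
        for _ in range(30):
            mir = random_rna(rng, int(rng.integers(15, 23)))
            site = random_rna(rng, len(mir) + int(rng.integers(-2, 3)))
            a = align_duplex(mir, site, flat, enforce_bounds=False)
            b = align_duplex(mir[::-1], site[::-1], flat, enforce_bounds=False)
            assert a.allen_score == b.allen_score


class TestDuplexEnergies:
    def test_perfect_duplex_site_energy_equals_perfect_energy(self):
        mir = "UGCCAAAGGAGAAUUGCCCUG"
        aln = align_duplex(mir, reverse_complement(mir))
        assert aln.mfe_site == aln.mfe_perfect

    def test_one_mismatch_costs_exactly_that_pair_energy(self):
        mir = "GGGGGAAAAAGGGGGAAAAA"
        perfect = reverse_complement(mir)
        # break the pair opposite miR position 16 (A:U, -2), outside the core
        mutated = perfect[:4] + "A" + perfect[5:]
        a0 = align_duplex(mir, perfect)
        a1 = align_duplex(mir, mutated)
        assert a1.mfe_site - a0.mfe_site == 2.0
        assert a1.mfe_perfect == a0.mfe_perfect

    def test_printed_mir414_duplex_column_sum(self):
        aln_site, aln_mir = MIR414_SITE, MIR414_MIR_3TO5
        # hand recount: per paired column GC -3 / AU -2 / GU -1
        from shademir.rnautil import is_paired, pair_energy

        expected = sum(
            pair_energy(s, m)
            for s, m in zip(aln_site, aln_mir)
            if is_paired(s, m)
        )
        from shademir.targets import DuplexAlignment

        aln = DuplexAlignment(
            "miR414", "t", 1, 20, aln_site, aln_mir, "", 4.5, 0, 0, 10
        )
        mfe_site, mfe_perfect = duplex_energies(aln)
        assert mfe_site == expected
        assert mfe_perfect <= mfe_site <= 0


class TestExtractQuery:
    def test_lower_edge_window(self):
        t = "A" * 30
        assert extract_query(t, 14)[:2] == (1, 26)

    def test_underflow_rejected(self):
        assert extract_query("A" * 30, 13) is None

    def test_interior_window_coordinates(self):
        t = "ACGU" * 15
        start, end, seq = extract_query(t, 20)
        assert (start, end) == (7, 32)
        assert seq == t[6:32]


class TestScanTargets:
    def test_planted_perfect_site_found_once(self, rng):
        mir = random_rna(rng, 21)
        site = reverse_complement(mir)
        t = random_rna(rng, 200) + site + random_rna(rng, 200)
        hits = scan_targets(mir, {"tx": t}, score_threshold=3.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.allen_score == 0.0
        assert (h.t_start, h.t_stop) == (201, 221)
        assert h.expected_cs == h.t_stop - 9

    def test_random_transcript_has_no_perfect_site(self):
        rng = np.random.default_rng(11)
        mir = random_rna(rng, 21)
        t = random_rna(rng, 1000)
        assert scan_targets(mir, {"tx": t}, score_threshold=0.0) == []

    def test_threshold_selects_exactly_designed_scores(self, rng):
        from shademir.simulate import _plant_site
        from shademir.targets import DEFAULT_PARAMS

        mir = random_rna(rng, 21)
        designed = [2.0, 4.0, 6.0, 8.0]
        sites = [_plant_site(rng, mir, s, DEFAULT_PARAMS) for s in designed]
        spacer = lambda: random_rna(rng, 60)
        t = spacer()
        starts = []
        for s in sites:
            starts.append(len(t) + 1)
            t += s + spacer()
        hits = scan_targets(mir, {"tx": t}, score_threshold=7.0)
        got = sorted((h.t_start, h.allen_score) for h in hits)
        want = sorted(
            (st, sc) for st, sc in zip(starts, designed) if sc <= 7.0
        )
        assert got == want

    def test_scan_order_invariant_and_deterministic(self, rng):
        mir = random_rna(rng, 21)
        txs = {f"t{i}": random_rna(rng, 300) for i in range(4)}
        txs["t2"] = txs["t2"][:100] + reverse_complement(mir) + txs["t2"][121:]
        a = scan_targets(mir, txs, 7.0)
        b = scan_targets(mir, dict(reversed(list(txs.items()))), 7.0)
        assert [(h.transcript_id, h.t_start, h.allen_score) for h in a] == [
            (h.transcript_id, h.t_start, h.allen_score) for h in b
        ]

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            scan_targets("A" * 21, {}, 7.0)

    def test_gapless_scores_match_align_duplex_on_gapless_optimum(self, rng):
        mir = random_rna(rng, 20)
        t = random_rna(rng, 120)
        scores = gapless_scores(mir, t)
        assert scores.shape == (101,)
        for o in (0, 50, 100):
            aln = align_duplex(mir, t[o : o + 20], enforce_bounds=False)
            assert aln.allen_score <= scores[o]
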