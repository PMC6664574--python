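"""Motif validity rules, site scanning and window enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triplexmotif import (
    MotifCriteria,
    complement,
    enumerate_motif_windows,
    find_motif_sites,
    invert_region,
    is_valid_motif,
)

from conftest import brute_force_sites, brute_force_windows, coords, make_seq


class TestValidity:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("uuucu", True),  # one of the four 5-mers of uuucuuccuu
            ("uucuu", True),
            ("uuccu", True),
            ("uccuu", True),
            ("ucuuc", False),  # only 2 nt between first and last U
            ("uuuuc", False),  # four Us in a row
            ("ucccu", False),  # three Cs in a row
            ("uuuu", False),  # shorter than 5
            ("UTCTT", True),  # U and T interchangeable
        ],
    )
    def test_pyrimidine_hoogsteen_rules(self, motif, expected, uc_criteria):
        assert is_valid_motif(motif, uc_criteria) is expected

    def test_purine_reverse_hoogsteen_allows_long_g_runs(self, ag_criteria):
        assert is_valid_motif("aggaagaaggga", ag_criteria)  # AG-12a
        assert is_valid_motif("aggaagagggga", ag_criteria)  # AG-12b, G4 run
        assert is_valid_motif("aggaagaaggaa", ag_criteria)  # AG-12c
        # Hoogsteen-mode purine criteria keep the 2-G limit
        assert not is_valid_motif("aggaagagggga", MotifCriteria.ag_hoogsteen())

    def test_n_breaks_motifs_and_foreign_residues_raise(self, uc_criteria):
        assert not is_valid_motif("TTNCT", uc_criteria)
        assert not is_valid_motif("TTACT", uc_criteria)  # other-class base
        with pytest.raises(ValueError):
            is_valid_motif("TTXCT", uc_criteria)
        with pytest.raises(ValueError):
            is_valid_motif("", uc_criteria)

    def test_criteria_invariants_enforced(self):
        with pytest.raises(ValueError):
            MotifCriteria(min_length=4, min_internal_gap=3)
        with pytest.raises(ValueError):
            MotifCriteria(max_anchor_run=0)


class TestSites:
    def test_single_minimal_site(self, uc_criteria):
        sites = find_motif_sites(make_seq("aaUUUCUaa"), uc_criteria)
        assert coords(sites) == [(2, 7)]
        assert sites[0].sequence == "TTTCT"

    def test_run_violating_a_rule_yields_its_maximal_valid_subwindow(self, uc_criteria):
        # TCTTTTC as a whole has four Ts in a row; TCTTT survives
        sites = find_motif_sites(make_seq("UCUUUUC"), uc_criteria)
        assert [(s.start, s.end, s.sequence) for s in sites] == [(0, 5, "TCTTT")]

    def test_no_sites_in_mixed_sequence(self, uc_criteria):
        assert find_motif_sites(make_seq("ACGACG"), uc_criteria) == []

    @pytest.mark.parametrize("anchor_bounded", [False, True])
    @pytest.mark.parametrize("alphabet", ["ACGT", "TCA", "TTTCCA"])
    def test_scanner_equals_brute_force(self, rng, uc_criteria, anchor_bounded, alphabet):
        """Maximal sites match enumerate-then-remove-contained on random input."""
        from dataclasses import replace

        crit = replace(uc_criteria, anchor_bounded=anchor_bounded)
        for _ in range(120):
            s = "".join(rng.choice(list(alphabet), size=rng.integers(5, 61)))
            seq = make_seq(s)
            assert coords(find_motif_sites(seq, crit)) == brute_force_sites(s, crit)

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="TCAG", min_size=5, max_size=50))
    def test_scanner_equals_brute_force_hypothesis(self, s):
        crit = MotifCriteria.ag_reverse_hoogsteen()
        assert coords(find_motif_sites(make_seq(s), crit)) == brute_force_sites(s, crit)

    def test_sites_are_valid_maximal_and_in_bounds(self, rng, ag_criteria):
        for _ in range(40):
            s = "".join(rng.choice(list("AGTN"), size=60))
            sites = find_motif_sites(make_seq(s), ag_criteria)
            spans = coords(sites)
            for site in sites:
                assert 0 <= site.start < site.end <= len(s)
                assert "N" not in site.sequence
                assert is_valid_motif(site.sequence, ag_criteria)
            for a in spans:
                assert not any(b != a and b[0] <= a[0] and a[1] <= b[1] for b in spans)


class TestWindows:
    def test_worked_ten_mer_contains_four_five_mers(self, uc_criteria):
        wins = enumerate_motif_windows(make_seq("uuucuuccuu"), uc_criteria, (5, 5))
        assert [w.sequence for w in wins] == ["TTTCT", "TTCTT", "TTCCT", "TCCTT"]

    def test_all_lengths_include_the_full_ten_mer(self, uc_criteria):
        wins = enumerate_motif_windows(make_seq("uuucuuccuu"), uc_criteria)
        seqs = {w.sequence for w in wins}
        assert "TTTCTTCCTT" in seqs and {"TTTCT", "TTCTT", "TTCCT", "TCCTT"} <= seqs

    def test_empty_for_motif_free_sequence(self, uc_criteria):
        assert enumerate_motif_windows(make_seq("ACGT"), uc_criteria) == []

    def test_windows_equal_brute_force(self, rng, uc_criteria, ag_criteria):
        for crit, alphabet in ((uc_criteria, "TCAG"), (ag_criteria, "AGTC")):
            for _ in range(60):
                s = "".join(rng.choice(list(alphabet), size=rng.integers(5, 50)))
                got = [(w.start, w.end) for w in enumerate_motif_windows(make_seq(s), crit)]
                assert sorted(got) == brute_force_windows(s, crit)


class TestInversionAndComplement:
    def test_reverse_complement_of_region(self):
        assert invert_region(make_seq("AAGGG"), 2, 5).residues == "AACCC"

    def test_double_inversion_is_identity(self, rng):
        s = make_seq("".join(rng.choice(list("ACGT"), size=100)))
        twice = invert_region(invert_region(s, 10, 60), 10, 60)
        assert twice.residues == s.residues

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            invert_region(make_seq("ACGT"), 2, 9)

    def test_inversion_swaps_motif_classes(self, uc_criteria, ag_criteria):
        # a UC motif inside the inverted region reappears as an AG motif
        s = make_seq("GG" + "TTTCTTCCTT" + "GG")
        inv = invert_region(s, 0, len(s.residues))
        before_uc = find_motif_sites(s, uc_criteria)
        after_ag = find_motif_sites(inv, ag_criteria)
        assert len(before_uc) == 1 and len(after_ag) == 1
        assert after_ag[0].sequence == "AAGGAAGAAA"

    def test_complement_duality_of_scans(self, rng, uc_criteria):
        """UC sites on S coincide with AG sites on the base-complement of S
        when the partner-run limit is mirrored."""
        ag_mirror = uc_criteria.complementary()  # AG criteria, max G run = 2
        for _ in range(50):
            s = make_seq("".join(rng.choice(list("ACGT"), size=80)))
            assert coords(find_motif_sites(s, uc_criteria)) == coords(
                find_motif_sites(complement(s), ag_mirror)
            )
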