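"""Occupancy profiles, length distributions, KS distance, repeat statistics."""

import numpy as np
import pytest

from triplexmotif import (
    KS_SIMILARITY_THRESHOLD,
    LengthDistribution,
    MotifSite,
    NucleotideSequence,
    cumulative_short_motif_ratio,
    enumerate_motif_windows,
    family_proportions,
    ks_distance,
    length_distribution,
    make_length_bins,
    profile_sequence,
    sample_by_length_bin,
    similar,
    union_coverage,
)
from triplexmotif.io import RepeatAnnotation
from triplexmotif.scan import MotifCriteria
from triplexmotif.stats import assign_length_bin

from conftest import make_seq


def _site(start, end, cls="UC"):
    return MotifSite("s", start, end, cls, "T" * (end - start))


class TestProfile:
    def test_counts_occupancy_frequency(self):
        # one 10-nt UC site in a 100-nt motif-free background (no A anywhere,
        # and G/C runs too short to hold a motif)
        seq = NucleotideSequence("x", "CCGGG" * 9 + "TTTCTTCCTT" + "GGGCC" * 9)
        p = profile_sequence(seq)
        assert p.seq_length == 100
        assert p.site_count["UC"] == 1 and p.site_count["AG"] == 0
        assert p.occupancy["UC"] == pytest.approx(0.10)
        assert p.frequency["UC"] == pytest.approx(10.0)  # 1 site / 0.1 kb
        assert p.ratio_uc_over_ag is None  # AG occupancy is zero

    def test_union_rule_for_overlapping_sites(self):
        assert union_coverage([_site(0, 8), _site(4, 12)]) == 12
        assert union_coverage([_site(0, 8), _site(20, 24)]) == 12
        assert union_coverage([]) == 0

    def test_union_equals_per_position_count(self, rng):
        for _ in range(30):
            sites = [
                _site(a, a + int(l))
                for a, l in zip(rng.integers(0, 90, 12), rng.integers(1, 10, 12))
            ]
            mask = np.zeros(100, dtype=bool)
            for s in sites:
                mask[s.start : s.end] = True
            assert union_coverage(sites) == int(mask.sum())

    def test_ratio_from_unrounded_occupancies(self):
        # UC covers 10 nt, AG covers 5 nt of a 100-nt sequence -> ratio 2.0
        seq = NucleotideSequence(
            "x", "CCGGG" * 4 + "TTTCTTCCTT" + "GGGCC" * 4 + "AGGGA" + "CCGGG" * 9
        )
        p = profile_sequence(seq)
        assert p.occupancy["UC"] == pytest.approx(0.10)
        assert p.occupancy["AG"] == pytest.approx(0.05)
        assert p.ratio_uc_over_ag == pytest.approx(2.0)

    def test_zero_length_sequence_rejected(self):
        with pytest.raises(ValueError):
            profile_sequence(NucleotideSequence("x", ""))


class TestLengthDistribution:
    def test_counts_and_cdf(self):
        d = length_distribution([_site(0, 5), _site(10, 15), _site(20, 27)])
        assert d.counts == {5: 2, 7: 1}
        assert d.n == 3
        assert d.cdf(5) == pytest.approx(2 / 3)
        assert d.cdf(6) == pytest.approx(2 / 3)
        assert d.cdf(7) == 1.0

    def test_empty(self):
        d = length_distribution([])
        assert d.n == 0
        with pytest.raises(ValueError):
            d.cdf(5)

    def test_single_length_mass(self):
        d = length_distribution([_site(0, 12, "AG")] * 141)
        assert d.counts == {12: 141}


class TestKSDistance:
    def test_identical_is_zero(self):
        d = LengthDistribution({5: 3, 7: 2})
        assert ks_distance(d, d) == 0.0

    def test_disjoint_supports_is_one(self):
        assert ks_distance(LengthDistribution({5: 1}), LengthDistribution({6: 1})) == 1.0

    def test_half_overlap(self):
        d1 = LengthDistribution({5: 1, 6: 1})
        d2 = LengthDistribution({5: 1, 7: 1})
        assert ks_distance(d1, d2) == pytest.approx(0.5)  # difference at x=6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_distance(LengthDistribution({}), LengthDistribution({5: 1}))

    def test_similarity_threshold(self):
        d1 = LengthDistribution({5: 100, 6: 100})
        d2 = LengthDistribution({5: 105, 6: 95})
        assert similar(d1, d2) and ks_distance(d1, d2) < KS_SIMILARITY_THRESHOLD

    def test_metric_axioms_on_random_distributions(self, rng):
        def random_dist():
            lengths = rng.choice(np.arange(5, 18), size=rng.integers(1, 8), replace=False)
            return LengthDistribution({int(l): int(rng.integers(1, 50)) for l in lengths})

        for _ in range(200):
            a, b, c = random_dist(), random_dist(), random_dist()
            dab, dba = ks_distance(a, b), ks_distance(b, a)
            assert dab == pytest.approx(dba)  # symmetry
            assert 0.0 <= dab <= 1.0
            # identity of indiscernibles on the CDF
            if dab == 0.0:
                na, nb = a.n, b.n
                assert {l: ct / na for l, ct in a.counts.items()} == {
                    l: ct / nb for l, ct in b.counts.items()
                }
            assert ks_distance(a, c) <= dab + ks_distance(b, c) + 1e-12  # triangle


class TestCumulativeRatio:
    def test_all_short(self):
        wins = [_site(0, 5)] * 4
        assert cumulative_short_motif_ratio(wins, (5, 7)) == 1.0

    def test_worked_ten_mer(self, uc_criteria):
        wins = enumerate_motif_windows(make_seq("uuucuuccuu"), uc_criteria)
        short = sum(1 for w in wins if 5 <= w.length <= 7)
        assert cumulative_short_motif_ratio(wins, (5, 7)) == pytest.approx(short / len(wins))
        assert cumulative_short_motif_ratio(wins, (5, 10)) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_short_motif_ratio([], (5, 7))


def _ann(chrom, start, end, family="L1", strand="+"):
    return RepeatAnnotation(chrom, start, end, strand, "LINE", family, f"{family}_x")


class TestFamilyProportions:
    def test_basic_proportion(self):
        df = family_proportions([_ann("chrX", 0, 1000)], {"chrX": 10_000})
        assert df.loc["chrX", "L1"] == pytest.approx(0.10)

    def test_missing_family_is_zero(self):
        df = family_proportions(
            [_ann("chrX", 0, 1000), _ann("chr1", 0, 500, "L2")],
            {"chrX": 10_000, "chr1": 10_000},
        )
        assert df.loc["chrX", "L2"] == 0.0
        assert df.loc["chr1", "L2"] == pytest.approx(0.05)

    def test_overlapping_records_warn(self):
        with pytest.warns(UserWarning, match="overlapping"):
            df = family_proportions(
                [_ann("chrX", 0, 1000), _ann("chrX", 500, 1500)], {"chrX": 10_000}
            )
        assert df.loc["chrX", "L1"] == pytest.approx(0.20)  # raw summed lengths

    def test_annotation_beyond_chromosome_end_raises(self):
        with pytest.raises(ValueError):
            family_proportions([_ann("chrX", 0, 20_000)], {"chrX": 10_000})

    def test_sums_at_most_one_on_nonoverlapping_fixtures(self, rng):
        anns, pos = [], 0
        for i in range(50):
            l = int(rng.integers(50, 400))
            anns.append(_ann("chrX", pos, pos + l, rng.choice(["L1", "L2", "CR1"])))
            pos += l + int(rng.integers(1, 100))
        df = family_proportions(anns, {"chrX": pos})
        assert df.sum(axis=1).iloc[0] <= 1.0


class TestLengthBins:
    def test_bin_edges_right_closed(self):
        bins = make_length_bins(3000)
        assert bins[0] == (0, 100) and bins[9] == (900, 1000)
        assert bins[10] == (1000, 2000)
        assert assign_length_bin(100, bins) == 0  # "<=100"
        assert assign_length_bin(101, bins) == 1  # "101-200"
        assert assign_length_bin(1000, bins) == 9
        assert assign_length_bin(1001, bins) == 10

    def test_sampling_reproducible_and_without_replacement(self):
        anns = [_ann("chrX", i * 100, i * 100 + 50) for i in range(200)]
        bins = [(0, 100)]
        s1 = sample_by_length_bin(anns, bins, 50, seed=11)
        s2 = sample_by_length_bin(anns, bins, 50, seed=11)
        assert s1 == s2 and len(s1) == 50
        assert len({(a.start, a.end) for a in s1}) == 50
        s3 = sample_by_length_bin(anns, bins, 50, seed=12)
        assert s3 != s1  # different seeds -> generally different samples

    def test_small_bin_returns_all(self):
        anns = [_ann("chrX", i * 10_000, i * 10_000 + 7500) for i in range(4)]
        bins = [(7000, 8000)]
        assert len(sample_by_length_bin(anns, bins, 50, seed=1)) == 4

    def test_empty_bin_set_rejected(self):
        with pytest.raises(ValueError):
            sample_by_length_bin([], [], 50, seed=1)
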