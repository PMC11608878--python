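import math

import numpy as np
import pytest

from hzdiv.locus_io import LocusMetadata
from hzdiv.stats import (
    SiteFilterPolicy,
    compute_locus_stats,
    dxy,
    fst,
    harmonic_a1,
    nucleotide_diversity,
    segregating_sites,
    tajimas_d,
    usable_sites,
    wattersons_theta,
)

from conftest import make_alignment, random_haplotypes
from oracles import (
    brute_dxy,
    brute_fst,
    brute_pi,
    brute_segregating_sites,
    brute_tajimas_d,
    brute_theta_w,
    usable_columns,
)


class TestUsableSites:
    def test_no_missing_keeps_all(self):
        assert list(usable_sites(["ACGT", "ACGA"])) == [0, 1, 2, 3]

    def test_single_n_drops_column(self):
        assert list(usable_sites(["ACGNT", "ACGTT"])) == [0, 1, 2, 4]

    def test_gap_policy(self):
        seqs = ["AC-T", "ACGT"]
        assert list(usable_sites(seqs)) == [0, 1, 3]
        keep_gaps = SiteFilterPolicy(treat_gap_as_missing=False)
        assert list(usable_sites(seqs, keep_gaps)) == [0, 1, 2, 3]

    def test_matches_column_scan(self, rng):
        for _ in range(500):
            seqs = random_haplotypes(
                rng, int(rng.integers(2, 8)), int(rng.integers(4, 40))
            )
            assert list(usable_sites(seqs)) == usable_columns(seqs)


class TestWorkedExamples:
    def test_identical_sequences_pi_zero(self):
        assert nucleotide_diversity(["ACGT" * 3] * 4) == 0.0

    def test_single_pair_one_difference(self):
        assert nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAAAT"]) == pytest.approx(0.1)

    def test_two_two_split_site(self):
        # alleles A,A,T,T at 1 of 10 sites: 4 differing pairs of 6
        seqs = ["A" * 10, "A" * 10, "T" + "A" * 9, "T" + "A" * 9]
        assert nucleotide_diversity(seqs) == pytest.approx((4 / 6) / 10)

    def test_harmonic_a1_n4(self):
        assert harmonic_a1(4) == pytest.approx(11 / 6, abs=1e-15)

    def test_theta_no_variation(self):
        assert wattersons_theta(["ACGT"] * 5) == 0.0
        assert segregating_sites(["ACGT"] * 5) == 0

    def test_tajima_undefined_without_variation(self):
        assert math.isnan(tajimas_d(["ACGT" * 5] * 6))

    def test_tajima_undefined_small_n(self):
        assert math.isnan(tajimas_d(["ACGT", "ACGA", "ACGT"]))

    def test_singleton_excess_negative_d(self, rng):
        # every variant private to one sequence -> rare-variant excess
        n, L = 20, 200
        base = "A" * L
        seqs = [base] * (n - 10)
        for i in range(10):
            seqs = seqs + [base[: i * 3] + "T" + base[i * 3 + 1 :]]
        assert tajimas_d(seqs) < 0

    def test_dxy_fixed_difference(self):
        a = ["A" + "C" * 9] * 3
        b = ["T" + "C" * 9] * 3
        assert dxy(a, b) == pytest.approx(0.1)

    def test_dxy_identical_groups(self):
        seqs = ["ACGT" * 5] * 3
        assert dxy(seqs, seqs) == 0.0

    def test_fst_reciprocal_fixation(self):
        a = ["A" * 10] * 3
        b = ["T" + "A" * 9] * 3
        assert fst(a, b) == 1.0

    def test_fst_same_pool_shrinks_with_n(self):
        # comparing a pool against itself: Hb keeps the zero self-pairs,
        # so Fst(a, a) = -1/(n-1) exactly and vanishes as n grows
        pool = ["ACGT" * 4, "ACGA" * 4]
        for reps in (2, 5, 20):
            group = pool * reps
            n = len(group)
            assert fst(group, group) == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_fst_nan_when_no_divergence(self):
        seqs = ["ACGT"] * 4
        assert math.isnan(fst(seqs, seqs))


class TestOracleEquivalence:
    """Dual-route check: vectorised statistics vs pairwise enumeration."""

    def _random_case(self, rng):
        n = int(rng.integers(2, 13))
        L = int(rng.integers(5, 200))
        return random_haplotypes(rng, n, L, missing_rate=0.04, gap_rate=0.02)

    def test_within_statistics(self, rng):
        for _ in range(300):
            seqs = self._random_case(rng)
            if not usable_columns(seqs):
                continue
            assert nucleotide_diversity(seqs) == pytest.approx(
                brute_pi(seqs), abs=1e-12
            )
            assert segregating_sites(seqs) == brute_segregating_sites(seqs)
            assert wattersons_theta(seqs) == pytest.approx(
                brute_theta_w(seqs), abs=1e-12
            )
            d = tajimas_d(seqs)
            bd = brute_tajimas_d(seqs)
            if math.isnan(bd):
                assert math.isnan(d)
            else:
                assert d == pytest.approx(bd, abs=1e-12)

    def test_between_statistics(self, rng):
        for _ in range(300):
            a = self._random_case(rng)
            b = random_haplotypes(
                rng, int(rng.integers(2, 10)), len(a[0]), missing_rate=0.04
            )
            if not usable_columns(a + b):
                continue
            assert dxy(a, b) == pytest.approx(brute_dxy(a, b), abs=1e-12)
            f, bf = fst(a, b), brute_fst(a, b)
            if math.isnan(bf):
                assert math.isnan(f)
            else:
                assert f == pytest.approx(bf, abs=1e-12)


class TestInvariances:
    def test_order_invariance(self, rng):
        seqs = random_haplotypes(rng, 8, 60)
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert nucleotide_diversity(seqs) == nucleotide_diversity(shuffled)
        assert tajimas_d(seqs) == tajimas_d(shuffled)

    def test_identical_groups_exact_identities(self, rng):
        # Dxy(a, a) counts the n self-pairs at distance 0, giving
        # exactly pi * (n-1)/n; the corresponding Fst is -1/(n-1)
        for _ in range(50):
            seqs = random_haplotypes(rng, 6, 50, missing_rate=0.0, gap_rate=0.0)
            n = len(seqs)
            pi = nucleotide_diversity(seqs)
            assert dxy(seqs, seqs) == pytest.approx(pi * (n - 1) / n, abs=1e-12)
            if pi > 0:
                assert fst(seqs, seqs) == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_hw_hb_identity(self, rng):
        # Hw = (1 - Fst) * Hb holds exactly by construction
        for _ in range(50):
            a = random_haplotypes(rng, 5, 40)
            b = random_haplotypes(rng, 5, 40)
            f = fst(a, b)
            if math.isnan(f):
                continue
            cols = [
                j
                for j in range(40)
                if all(s[j] not in "N-" for s in a + b)
            ]
            sub_a = ["".join(s[j] for j in cols) for s in a]
            sub_b = ["".join(s[j] for j in cols) for s in b]
            hw = (nucleotide_diversity(sub_a) + nucleotide_diversity(sub_b)) / 2
            hb = dxy(sub_a, sub_b)
            assert hw == pytest.approx((1 - f) * hb, abs=1e-12)

    def test_negative_fst_not_clipped(self):
        # within-group diversity above between-group: estimator goes negative
        a = ["AAAA", "TTTT"]
        b = ["AAAA", "TTTT"]
        assert fst(a, b) < 0 or fst(a, b) == 0.0


class TestNstVariant:
    def test_nst_agrees_on_strong_structure(self):
        a = ["A" * 10] * 4
        b = ["T" + "A" * 9] * 4
        assert fst(a, b, estimator="nst") > 0.75

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ValueError, match="estimator"):
            fst(["AC", "AC"], ["AG", "AG"], estimator="bogus")


class TestComputeLocusStats:
    def test_single_species_has_no_divergence_fields(self):
        aln = make_alignment(["ACGT" * 5, "ACGA" * 5], ["sp1", "sp1"])
        st = compute_locus_stats(aln)
        assert math.isnan(st.dxy) and math.isnan(st.fst)
        assert st.per_species["sp1"].pi > 0

    def test_two_species_all_fields(self, rng):
        seqs = random_haplotypes(rng, 12, 100, missing_rate=0.01, gap_rate=0.0)
        aln = make_alignment(seqs, ["sp1"] * 6 + ["sp2"] * 6)
        st = compute_locus_stats(aln, LocusMetadata("locus1", "X", "introgressing"))
        assert st.linkage == "X"
        assert not math.isnan(st.dxy)
        groups = aln.by_species()
        assert st.dxy == pytest.approx(brute_dxy(groups["sp1"], groups["sp2"]), abs=1e-12)
        assert st.per_species["sp1"].pi == pytest.approx(
            brute_pi(groups["sp1"]), abs=1e-12
        )

    def test_matches_oracles_on_random_loci(self, rng):
        for _ in range(200):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            L = int(rng.integers(10, 80))
            seqs = random_haplotypes(rng, n1 + n2, L)
            aln = make_alignment(seqs, ["sp1"] * n1 + ["sp2"] * n2)
            st = compute_locus_stats(aln)
            g = aln.by_species()
            if usable_columns(g["sp1"]):
                assert st.per_species["sp1"].s == brute_segregating_sites(g["sp1"])
            if usable_columns(g["sp1"] + g["sp2"]):
                bd = brute_dxy(g["sp1"], g["sp2"])
                assert st.dxy == pytest.approx(bd, abs=1e-12)
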