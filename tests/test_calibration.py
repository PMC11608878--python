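import math

import numpy as np
import pytest

from hzdiv.calibration import (
    calibrate_locus,
    consensus_divergence,
    divergence_time,
    locus_mutation_rate,
    species_consensus,
)
from hzdiv.fourgamete import (
    incompatible_pairs,
    longest_compatible_block,
    trim_to_block,
)
from hzdiv.im_format import parse_im_input, write_im_input
from hzdiv.locus_io import LocusMetadata
from hzdiv.simulate import SimConfig, simulate_recombinant_locus

from conftest import make_alignment, random_haplotypes
from oracles import brute_longest_block, brute_window_compatible


class TestSpeciesConsensus:
    def test_single_sequence_is_itself(self):
        assert species_consensus(["ACGTN"]) == "ACGTN"

    def test_majority_wins(self):
        assert species_consensus(["AAT", "AAT", "ATT"]) == "AAT"

    def test_two_way_tie_reported_as_iupac(self):
        assert species_consensus(["AA", "AA", "TA", "TA"]) == "WA"

    def test_missing_ignored(self):
        assert species_consensus(["ANG", "A-G", "ACG"]) == "ACG"

    def test_no_called_base_is_n(self):
        assert species_consensus(["N-", "NN"]) == "NN"


class TestConsensusDivergence:
    def test_identical(self):
        assert consensus_divergence("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_one_diff_in_hundred(self):
        a = "A" * 100
        b = "T" + "A" * 99
        assert consensus_divergence(a, b) == pytest.approx(0.01)

    def test_jukes_cantor_correction(self):
        # p = 0.0736 maps to 0.0776 under JC
        L = 10_000
        k = 736
        a = "A" * L
        b = "T" * k + "A" * (L - k)
        assert consensus_divergence(a, b, model="JC") == pytest.approx(
            -0.75 * math.log(1 - 4 * 0.0736 / 3), abs=1e-12
        )
        assert consensus_divergence(a, b, model="JC") == pytest.approx(0.0775, abs=5e-5)

    def test_ambiguous_sites_excluded(self):
        # the tied (IUPAC) consensus position carries no signal
        assert consensus_divergence("WAAA", "TAAA") == 0.0

    def test_no_comparable_sites_undefined(self):
        assert math.isnan(consensus_divergence("NNNN", "ACGT"))


class TestClockArithmetic:
    def test_zero_divergence_zero_time(self):
        assert divergence_time(0.0) == 0.0

    def test_worked_value_3_2_my(self):
        # the mtDNA divergence to the older outgroup dates to 3.2 My
        assert divergence_time(0.0736) == pytest.approx(3.2e6)

    def test_worked_value_200_ky(self):
        # the ingroup mtDNA split of ~200 Ky corresponds to D = 0.0046
        assert divergence_time(0.0046) == pytest.approx(0.2e6)

    def test_locus_rate_worked_value(self):
        assert locus_mutation_rate(0.026, 3.2e6) == pytest.approx(4.0625e-9)

    def test_mutual_inversion_exact(self, rng):
        for _ in range(200):
            d = float(rng.uniform(0, 0.2))
            mu_my = float(rng.uniform(0.001, 0.05))
            t = divergence_time(d, mu_my)
            if t == 0:
                continue
            back = locus_mutation_rate(d, t)
            assert back == pytest.approx(mu_my / 1e6, rel=1e-12)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            locus_mutation_rate(0.01, 0.0)


class TestCalibrateLocus:
    def test_two_outgroups_averaged(self):
        ing = "A" * 1000
        og1 = ["T" * 26 + "A" * 974]  # D=0.026 at t=3.2 My
        og2 = ["T" * 22 + "A" * 978]  # D=0.022 at t=2.7 My
        res = calibrate_locus(
            "L1", ing, {"G_bimaculatus": og1, "G_rubens": og2}
        )
        mu1 = 0.026 / (2 * 3.2e6)
        mu2 = 0.022 / (2 * 2.7e6)
        assert res.outgroups_used == 2
        assert res.mu_locus == pytest.approx((mu1 + mu2) / 2, rel=1e-12)

    def test_no_outgroup_gives_no_rate(self):
        res = calibrate_locus("L1", "ACGT", {})
        assert res.mu_locus is None
        assert res.outgroups_used == 0

    def test_zero_divergence_flagged(self):
        res = calibrate_locus("L1", "A" * 50, {"G_rubens": ["A" * 50]})
        assert res.mu_locus == 0.0
        assert res.implausible_zero


class TestFourGamete:
    def test_no_segregating_sites_whole_locus(self):
        block = longest_compatible_block(["ACGT" * 5] * 4, "L1")
        assert (block.start, block.end) == (0, 20)
        assert block.n_segregating_inside == 0

    def test_all_four_gametes_example(self):
        # sites 2 and 7 show AA, AT, TA, TT: one must be excluded and the
        # longest window has length 7; ties resolve leftmost -> [0, 7)
        seqs = []
        for g1, g2 in [("A", "A"), ("A", "T"), ("T", "A"), ("T", "T")]:
            s = list("C" * 10)
            s[2], s[7] = g1, g2
            seqs.append("".join(s))
        block = longest_compatible_block(seqs, "L1")
        assert (block.start, block.end) == (0, 7)

    def test_compatible_pair_keeps_everything(self):
        seqs = ["AACC", "AATT", "GGCC"]  # 3 gametes only at every pair
        block = longest_compatible_block(seqs, "L1")
        assert (block.start, block.end) == (0, 4)

    def test_matches_exhaustive_windows(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 9))
            L = int(rng.integers(4, 30))
            seqs = random_haplotypes(
                rng, n, L, missing_rate=0.03, gap_rate=0.01,
                n_variable=int(rng.integers(1, max(2, L // 2))),
            )
            block = longest_compatible_block(seqs, "L")
            bs, be = brute_longest_block(seqs)
            assert (block.start, block.end) == (bs, be), seqs

    def test_returned_block_always_compatible(self, rng):
        for _ in range(100):
            seqs = random_haplotypes(rng, 6, 40, n_variable=15)
            block = longest_compatible_block(seqs, "L")
            assert brute_window_compatible(seqs, block.start, block.end)

    def test_block_shrinks_with_recombination(self):
        """Concatenating independent gene trees (recombination) shortens
        the retained block relative to a single-tree locus, on average."""
        cfg = SimConfig(
            ne1=30_000, ne2=30_000, ne_anc=30_000, t_split=100_000,
            mu=2e-7, length=300, samples={"A": (0, 3), "B": (0, 3)},
        )
        single, recomb = [], []
        from dataclasses import replace

        for seed in range(60):
            aln, _ = __import__("hzdiv.simulate", fromlist=["simulate_locus"]).simulate_locus(
                replace(cfg, seed=seed)
            )
            single.append(longest_compatible_block(aln).length)
            rec, _, _ = simulate_recombinant_locus(replace(cfg, seed=seed))
            recomb.append(longest_compatible_block(rec).length)
        assert np.mean(recomb) < np.mean(single)


class TestImFormat:
    def _fixture(self, rng):
        seqs = random_haplotypes(rng, 8, 60, missing_rate=0.0, gap_rate=0.0)
        aln = make_alignment(seqs, ["sp1"] * 4 + ["sp2"] * 4, locus_id="loc1")
        meta = {"loc1": LocusMetadata("loc1", "X", "non_introgressing")}
        return aln, meta

    def test_header_shape_and_scalar(self, rng, tmp_path):
        aln, meta = self._fixture(rng)
        path = tmp_path / "im.txt"
        write_im_input([aln], meta, ("sp1", "sp2"), path,
                       mutation_rates={"loc1": 4.05e-9})
        lines = path.read_text().splitlines()
        assert lines[2] == "2"
        locus_line = lines[6].split()
        assert locus_line == ["loc1", "4", "4", "60", "I", "0.75", "4.05e-09"]

    def test_autosomal_scalar_is_one(self, rng, tmp_path):
        aln, _ = self._fixture(rng)
        meta = {"loc1": LocusMetadata("loc1", "autosomal", "introgressing")}
        path = tmp_path / "im.txt"
        write_im_input([aln], meta, ("sp1", "sp2"), path)
        assert path.read_text().splitlines()[6].split()[5] == "1"

    def test_unknown_linkage_needs_default(self, rng, tmp_path):
        aln, _ = self._fixture(rng)
        meta = {"loc1": LocusMetadata("loc1", "unknown", "unclassified")}
        with pytest.raises(ValueError, match="unknown linkage"):
            write_im_input([aln], meta, ("sp1", "sp2"), tmp_path / "x.txt")
        write_im_input([aln], meta, ("sp1", "sp2"), tmp_path / "y.txt",
                       default_scalar=1.0)

    def test_roundtrip(self, rng, tmp_path):
        aln, meta = self._fixture(rng)
        path = tmp_path / "im.txt"
        write_im_input([aln], meta, ("sp1", "sp2"), path,
                       mutation_rates={"loc1": 3.9e-9})
        parsed = parse_im_input(path)
        assert parsed["n_populations"] == 2
        assert parsed["populations"] == ["sp1", "sp2"]
        locus = parsed["loci"][0]
        assert locus.name == "loc1"
        assert locus.n_per_pop == (4, 4)
        assert locus.length == 60
        assert locus.model == "I"
        assert locus.inheritance == 0.75
        assert locus.mu_per_year == pytest.approx(3.9e-9)
        assert [s for _, s in locus.sequences] == aln.seqs()

    def test_missing_rate_field_omitted(self, rng, tmp_path):
        aln, meta = self._fixture(rng)
        path = tmp_path / "im.txt"
        write_im_input([aln], meta, ("sp1", "sp2"), path)  # no rates
        assert parse_im_input(path)["loci"][0].mu_per_year is None
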