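import math

import numpy as np
import pytest

import _oracles as oracle
from matloci.errors import ValidationError
from matloci.popgen import (
    NG86Pair,
    TajimaConstants,
    dxy,
    gene_record,
    hudson_fst,
    mean_pairwise_differences,
    ng86_pairwise,
    nucleotide_diversity,
    segregating_sites,
    tajimas_d,
    tajimas_d_from_alignment,
)

from conftest import make_alignment, random_alignment


class TestSegregatingSites:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            ({"A1": "ACGT", "A2": "ACGT"}, 0),
            ({"A1": "ACGT", "A2": "ACGA"}, 1),
            # gap column dropped (complete deletion), S over remaining 3 cols
            ({"A1": "AC-T", "A2": "ACGA"}, 1),
        ],
    )
    def test_stated_examples(self, seqs, expected):
        aln = make_alignment(seqs)
        assert segregating_sites(aln, list(seqs)) == expected

    def test_requires_two_strains(self):
        aln = make_alignment({"A1": "ACGT"})
        with pytest.raises(ValidationError):
            segregating_sites(aln, ["A1"])

    def test_matches_bruteforce_on_random_alignments(self, rng):
        for _ in range(50):
            aln = random_alignment(rng)
            strains = aln.strains
            assert segregating_sites(aln, strains) == (
                oracle.segregating_sites_bruteforce([aln.seqs[s] for s in strains])
            )


class TestPi:
    def test_two_seq_single_difference(self):
        s1 = "A" * 99 + "C"
        s2 = "A" * 99 + "G"
        aln = make_alignment({"A1": s1, "A2": s2})
        assert nucleotide_diversity(aln, ["A1", "A2"]) == pytest.approx(0.01)

    def test_identical_sequences_zero(self):
        aln = make_alignment({f"A{i}": "ACGTACGT" for i in range(4)})
        assert nucleotide_diversity(aln, aln.strains) == 0.0

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            aln = random_alignment(rng, n=4, L=40)
            got = nucleotide_diversity(aln, aln.strains)
            exp = oracle.pi_bruteforce([aln.seqs[s] for s in aln.strains])
            assert got == pytest.approx(exp, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, n=5, L=30)
            v = nucleotide_diversity(aln, aln.strains)
            assert 0.0 <= v <= 1.0


class TestDxy:
    def test_single_pair_quarter(self):
        aln = make_alignment({"A1": "AAAA", "B1": "AAAT"})
        assert dxy(aln, ["A1"], ["B1"]) == pytest.approx(0.25)

    def test_identical_species_zero(self):
        aln = make_alignment({"A1": "ACGT", "B1": "ACGT"})
        assert dxy(aln, ["A1"], ["B1"]) == 0.0

    def test_empty_set_raises(self):
        aln = make_alignment({"A1": "ACGT", "B1": "ACGT"})
        with pytest.raises(ValidationError):
            dxy(aln, [], ["B1"])

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            aln = random_alignment(rng, n=6, L=40)
            sa = aln.strains_of("speciesA")
            sb = aln.strains_of("speciesB")
            got = dxy(aln, sa, sb)
            exp = oracle.dxy_bruteforce(
                [aln.seqs[s] for s in sa], [aln.seqs[s] for s in sb]
            )
            assert got == pytest.approx(exp, abs=1e-12)


class TestFst:
    @pytest.mark.parametrize(
        "pi_a,pi_b,d,expected",
        [
            (0.0, 0.0, 0.02, 1.0),  # fixed differences
            (0.02, 0.02, 0.02, 0.0),  # panmixia limit
            (0.01, 0.03, 0.05, 0.6),
        ],
    )
    def test_formula(self, pi_a, pi_b, d, expected):
        assert hudson_fst(pi_a, pi_b, d) == pytest.approx(expected)

    def test_zero_dxy_is_null(self):
        assert hudson_fst(0.0, 0.0, 0.0) is None

    def test_negative_inputs_raise(self):
        with pytest.raises(ValidationError):
            hudson_fst(-0.01, 0.0, 0.1)

    def test_negative_fst_not_clamped(self):
        assert hudson_fst(0.03, 0.03, 0.02) < 0


class TestTajima:
    def test_zero_segregating_sites_is_null(self):
        assert tajimas_d(0, 0.0, 10) is None

    def test_constants_n4(self):
        c = TajimaConstants(4)
        assert c.a1 == pytest.approx(1 + 0.5 + 1 / 3)
        assert c.e1 > 0 and c.e2 > 0

    def test_singleton_alignment_negative_and_matches_transcription(self):
        # n=10, every variant a singleton: D must be negative
        seqs = {f"A{i:02d}": list("A" * 40) for i in range(10)}
        for i in range(1, 9):
            seqs[f"A{i:02d}"][i] = "C"  # 8 singleton sites
        aln = make_alignment({k: "".join(v) for k, v in seqs.items()})
        strains = aln.strains
        got = tajimas_d_from_alignment(aln, strains)
        S = oracle.segregating_sites_bruteforce([aln.seqs[s] for s in strains])
        k_hat = oracle.mean_pairwise_diff_bruteforce(
            [aln.seqs[s] for s in strains]
        )
        exp = oracle.tajima_d_transcription(S, k_hat, 10)
        assert got < 0
        assert got == pytest.approx(exp, abs=1e-9)

    def test_matches_transcription_on_random_triples(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            S = int(rng.integers(1, 80))
            k_hat = float(rng.uniform(0, S))
            assert tajimas_d(S, k_hat, n) == pytest.approx(
                oracle.tajima_d_transcription(S, k_hat, n), abs=1e-9
            )

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="n=2"):
            tajimas_d(3, 1.0, 2)


class TestNG86:
    def test_identical_sequences(self):
        pair = ng86_pairwise("TTTAAA", "TTTAAA")
        assert pair.syn_diffs == 0 and pair.nonsyn_diffs == 0
        assert pair.dS == 0 and pair.dN == 0

    def test_ten_phe_codons_hand_example(self):
        # 10x TTT vs 9x TTT + 1x TTC: one synonymous difference,
        # syn sites 10/3, pS = 0.3, dS = -0.75 ln(0.6)
        s1 = "TTT" * 10
        s2 = "TTT" * 9 + "TTC"
        pair = ng86_pairwise(s1, s2)
        assert pair.syn_diffs == pytest.approx(1.0)
        assert pair.syn_sites == pytest.approx(10 / 3)
        assert pair.pS == pytest.approx(0.3)
        assert pair.dS == pytest.approx(-0.75 * math.log(0.6))

    def test_single_codon_saturated_dS_is_null(self):
        pair = ng86_pairwise("TTT", "TTC")
        assert pair.syn_sites == pytest.approx(1 / 3)
        assert pair.pS == pytest.approx(3.0)
        assert pair.dS is None

    def test_site_counts_always_sum_to_three_per_codon(self, rng):
        for _ in range(30):
            a, b = _random_cds(rng, 10), _random_cds(rng, 10)
            pair = ng86_pairwise(a, b)
            assert pair.syn_sites + pair.nonsyn_sites == pytest.approx(
                3.0 * pair.codons_compared
            )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            a, b = _random_cds(rng, 15), _random_cds(rng, 15)
            pair = ng86_pairwise(a, b)
            syn, nonsyn, sd, nd, dS, dN = oracle.ng86_oracle(a, b)
            assert pair.syn_sites == pytest.approx(syn, abs=1e-9)
            assert pair.nonsyn_sites == pytest.approx(nonsyn, abs=1e-9)
            assert pair.syn_diffs == pytest.approx(sd, abs=1e-9)
            assert pair.nonsyn_diffs == pytest.approx(nd, abs=1e-9)
            if dS is None:
                assert pair.dS is None
            else:
                assert pair.dS == pytest.approx(dS, abs=1e-9)

    def test_gapped_codons_skipped_pairwise(self):
        pair = ng86_pairwise("TTT---AAA", "TTTAAAAAA")
        assert pair.codons_compared == 2

    def test_errors(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            ng86_pairwise("TTTA", "TTTA")
        with pytest.raises(ValidationError, match="stop"):
            ng86_pairwise("TAATTT", "AAATTT")


_SENSE = None


def _random_cds(rng, ncodons):
    global _SENSE
    if _SENSE is None:
        from itertools import product

        _SENSE = [
            "".join(p)
            for p in product("ACGT", repeat=3)
            if "".join(p) not in ("TAA", "TAG", "TGA")
        ]
    return "".join(rng.choice(_SENSE, size=ncodons))


class TestGeneRecord:
    def test_species_with_single_strain_gives_nulls(self):
        aln = make_alignment({"A1": "ACGTAA", "A2": "ACGTAA", "B1": "ACGTAT"})
        rec = gene_record(aln, "speciesA", "speciesB")
        assert rec.pi_b is None and rec.S_b is None
        assert rec.pi_a == 0.0
        assert rec.dxy is not None

    def test_pi_over_dxy_per_species(self, rng):
        aln = random_alignment(rng, n=8, L=60, gap_frac=0.0, n_frac=0.0)
        rec = gene_record(aln, "speciesA", "speciesB")
        assert rec.pi_over_dxy_a == pytest.approx(rec.pi_a / rec.dxy)
        assert rec.pi_over_dxy_b == pytest.approx(rec.pi_b / rec.dxy)
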