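from __future__ import annotations

import math

import numpy as np
import pytest

from dupmode.model import DupmodeError, DuplicatePair
from dupmode.rates import (CodonAlignment, SaturationError, align_codon_pair,
                           jukes_cantor, ng86_differences, ng86_sites,
                           pair_kaks, pairs2kaks)
from dupmode.simulate import simulate_codon_pair

from _oracles import SENSE, diffs_bruteforce, sites_bruteforce


def _codons(cds):
    return tuple(cds[i:i + 3] for i in range(0, len(cds), 3))


class TestSites:
    def test_phenylalanine(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3, abs=1e-12)
        assert n == pytest.approx(8 / 3, abs=1e-12)

    def test_methionine_has_no_synonymous_site(self):
        assert ng86_sites("ATG") == (0.0, 3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(DupmodeError):
            ng86_sites("TAA")

    def test_site_counts_sum_to_three(self):
        for codon in SENSE:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)
            ref_s, _ = sites_bruteforce(codon)
            assert s == pytest.approx(ref_s, abs=1e-12)


class TestDifferences:
    def test_single_synonymous_change(self):
        assert ng86_differences("TTT", "TTC") == (1.0, 0.0)

    def test_identical_codons(self):
        assert ng86_differences("TTT", "TTT") == (0.0, 0.0)

    def test_symmetry_and_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            c1, c2 = (SENSE[i] for i in rng.integers(0, len(SENSE), 2))
            sd, nd = ng86_differences(c1, c2)
            assert (sd, nd) == ng86_differences(c2, c1)
            k = sum(a != b for a, b in zip(c1, c2))
            assert sd + nd == pytest.approx(k, abs=1e-12)

    def test_two_difference_pairs_match_pathway_oracle(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 50:
            c1, c2 = (SENSE[i] for i in rng.integers(0, len(SENSE), 2))
            if sum(a != b for a, b in zip(c1, c2)) != 2:
                continue
            assert ng86_differences(c1, c2) == pytest.approx(
                diffs_bruteforce(c1, c2), abs=1e-12)
            checked += 1

    def test_stop_codon_rejected(self):
        with pytest.raises(DupmodeError):
            ng86_differences("TGA", "TGG")


class TestJukesCantor:
    def test_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)


class TestAlignment:
    def test_identical_pair(self):
        cds, _ = simulate_codon_pair(30, 0, 0, rng_seed=1)
        aln = align_codon_pair(cds, cds)
        assert aln.n_codons == 30
        assert aln.codons1 == aln.codons2

    def test_internal_deletion_drops_one_column(self):
        cds, _ = simulate_codon_pair(30, 0, 0, rng_seed=2)
        deleted = cds[:30] + cds[33:]  # drop codon 11
        aln = align_codon_pair(cds, deleted)
        assert aln.n_codons == 29

    def test_third_position_difference_retained(self):
        cds1, cds2 = simulate_codon_pair(30, 1, 0, rng_seed=3)
        aln = align_codon_pair(cds1, cds2)
        diffs = sum(a != b for a, b in zip("".join(aln.codons1),
                                           "".join(aln.codons2)))
        assert diffs == 1

    def test_trailing_stop_trimmed(self):
        cds, _ = simulate_codon_pair(30, 0, 0, rng_seed=4)
        aln = align_codon_pair(cds + "TAA", cds + "TGA")
        assert aln.n_codons == 30

    def test_frame_error(self):
        with pytest.raises(DupmodeError, match="divisible by 3"):
            align_codon_pair("ATGAA", "ATGAAA")

    def test_insufficient_codons(self):
        with pytest.raises(DupmodeError, match="insufficient"):
            align_codon_pair("ATGAAA", "ATGAAA")

    def test_inconsistent_protein_rejected(self):
        cds, _ = simulate_codon_pair(30, 0, 0, rng_seed=5)
        with pytest.raises(DupmodeError, match="inconsistent"):
            align_codon_pair(cds, cds, prot1="M" * 30)


class TestPairKaks:
    def test_identical_sequences(self):
        cds, _ = simulate_codon_pair(50, 0, 0, rng_seed=6)
        r = pair_kaks(align_codon_pair(cds, cds))
        assert r.ka == 0.0 and r.ks == 0.0 and r.ka_ks is None

    def test_synonymous_only_divergence(self):
        cds1, cds2 = simulate_codon_pair(100, 5, 0, rng_seed=7)
        r = pair_kaks(align_codon_pair(cds1, cds2))
        assert r.Sd == 5.0 and r.Nd == 0.0
        assert r.ka == 0.0
        assert r.ks == pytest.approx(jukes_cantor(5.0 / r.S), abs=1e-12)

    def test_site_conservation(self):
        cds1, cds2 = simulate_codon_pair(80, 6, 3, rng_seed=8)
        r = pair_kaks(align_codon_pair(cds1, cds2))
        assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_swap_symmetry(self):
        cds1, cds2 = simulate_codon_pair(60, 4, 4, rng_seed=9)
        r1 = pair_kaks(align_codon_pair(cds1, cds2))
        r2 = pair_kaks(align_codon_pair(cds2, cds1))
        assert (r1.ka, r1.ks, r1.S, r1.N) == (r2.ka, r2.ks, r2.S, r2.N)

    def test_unknown_model_lists_supported(self):
        aln = CodonAlignment(("AAA",) * 12, ("AAA",) * 12)
        with pytest.raises(DupmodeError, match="NG86"):
            pair_kaks(aln, model="GY94")

    def test_ks_nondecreasing_with_divergence(self):
        # expectation over replicates: more synonymous changes, larger Ks
        levels = (2, 8, 16, 24)
        means = []
        for level in levels:
            ks = []
            for rep in range(100):
                cds1, cds2 = simulate_codon_pair(100, level, 0,
                                                 rng_seed=1000 * level + rep)
                aln = CodonAlignment(_codons(cds1), _codons(cds2))
                ks.append(pair_kaks(aln).ks)
            means.append(sum(ks) / len(ks))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestPairs2Kaks:
    def test_matches_direct_calls_and_skips_missing(self):
        cds = {}
        pairs = []
        for i in range(3):
            c1, c2 = simulate_codon_pair(40, 3 + i, 1, rng_seed=20 + i)
            cds[f"a{i}"], cds[f"b{i}"] = c1, c2
            pairs.append(DuplicatePair(f"a{i}", f"b{i}", "TD"))
        pairs.append(DuplicatePair("zz", "a0", "DD"))  # no CDS for zz
        df = pairs2kaks(pairs, cds)
        assert len(df) == 3 and df.attrs["n_skipped"] == 1
        direct = pair_kaks(align_codon_pair(cds["a1"], cds["b1"]))
        row = df[df.gene1 == "a1"].iloc[0]
        assert row.Ks == direct.ks and row.Ka == direct.ka

    def test_thread_count_does_not_change_results(self):
        cds = {}
        pairs = []
        for i in range(4):
            c1, c2 = simulate_codon_pair(40, 5, 2, rng_seed=40 + i)
            cds[f"a{i}"], cds[f"b{i}"] = c1, c2
            pairs.append(DuplicatePair(f"a{i}", f"b{i}", "PD"))
        df1 = pairs2kaks(pairs, cds, threads=1)
        df2 = pairs2kaks(pairs, cds, threads=2)
        assert df1.equals(df2)
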