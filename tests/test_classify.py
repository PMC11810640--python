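from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupmode.classify import (ClassifyParams, classify_genes, classify_pairs,
                              duplicate_frequencies, singletons)
from dupmode.model import (DupmodeError, DuplicatePair, Paranome,
                           canonical_pair)

from conftest import make_index


def _paranome(*pairs):
    p = Paranome(species="sp")
    for a, b in pairs:
        p.add_hit(a, b, 1e-50, 500.0)
    return p


class TestStepwisePairClassification:
    def test_rank_distance_boundaries(self):
        index = make_index(20)
        paranome = _paranome(("g05", "g06"), ("g05", "g15"), ("g05", "g16"))
        pairs = {p.key: p.mode
                 for p in classify_pairs(paranome, index, set())}
        assert pairs[("g05", "g06")] == "TD"    # distance 1
        assert pairs[("g05", "g15")] == "PD"    # distance 10 == proximal_max
        assert pairs[("g05", "g16")] == "DD"    # distance 11

    def test_anchor_wins_over_adjacency(self):
        index = make_index(20)
        paranome = _paranome(("g05", "g06"))
        pairs = classify_pairs(paranome, index, {("g05", "g06")})
        assert pairs[0].mode == "SD"

    def test_binary_scheme_emits_sd_and_ssd(self):
        index = make_index(20)
        paranome = _paranome(("g01", "g02"), ("g03", "g10"))
        pairs = classify_pairs(paranome, index, {("g01", "g02")},
                               ClassifyParams(scheme="binary"))
        assert {p.mode for p in pairs} == {"SD", "SSD"}

    def test_proximal_max_is_adjustable(self):
        index = make_index(20)
        paranome = _paranome(("g05", "g10"))
        params = ClassifyParams(proximal_max=4)
        assert classify_pairs(paranome, index, set(), params)[0].mode == "DD"

    @pytest.mark.parametrize("n_ancestral,expected", [
        (3, "TRD"),   # 3/3 outgroups transposed
        (2, "DD"),    # 2/3 = 0.67 < 0.70
    ])
    def test_outgroup_fraction_threshold(self, n_ancestral, expected):
        index = make_index(40)
        paranome = _paranome(("g02", "g30"))
        outgroups = {}
        for i in range(3):
            # g02 ancestral, g30 not, in the first n_ancestral outgroups
            loci = {"g02"} if i < n_ancestral else {"g02", "g30"}
            outgroups[f"out{i}"] = loci
        pairs = classify_pairs(paranome, index, set(),
                               ClassifyParams(scheme="extended"), outgroups)
        assert pairs[0].mode == expected

    def test_both_or_neither_ancestral_stays_dispersed(self):
        index = make_index(40)
        paranome = _paranome(("g02", "g30"))
        for loci in ({"g02", "g30"}, set()):
            pairs = classify_pairs(paranome, index, set(),
                                   ClassifyParams(scheme="extended"),
                                   {"out1": loci})
            assert pairs[0].mode == "DD"

    @pytest.mark.parametrize("exons,expected", [
        ((1, 4), "rTRD"),   # exactly one intronless
        ((1, 1), "dTRD"),   # both intronless
        ((4, 3), "dTRD"),   # neither intronless
    ])
    def test_intronless_rule(self, exons, expected):
        counts = [2] * 40
        counts[1], counts[29] = exons
        index = make_index(40, exon_counts=counts)
        paranome = _paranome(("g02", "g30"))
        pairs = classify_pairs(paranome, index, set(),
                               ClassifyParams(scheme="full"),
                               {"out1": {"g02"}})
        assert pairs[0].mode == expected

    def test_extended_scheme_requires_outgroups(self):
        index = make_index(20)
        with pytest.raises(DupmodeError, match="outgroup"):
            classify_pairs(_paranome(("g01", "g05")), index, set(),
                           ClassifyParams(scheme="extended"))

    def test_unknown_gene_raises(self):
        index = make_index(5)
        with pytest.raises(DupmodeError, match="g99"):
            classify_pairs(_paranome(("g01", "g99")), index, set())

    def test_every_pair_labeled_exactly_once(self, paranome, full_pairs):
        assert sorted(p.key for p in full_pairs) == sorted(paranome.pair_set())


class TestSchemeNesting:
    def test_nesting_identities(self, dataset, paranome, anchor_pairs,
                                outgroup_ancestral):
        counts = {}
        for scheme in ("binary", "standard", "extended", "full"):
            pairs = classify_pairs(paranome, dataset.query, anchor_pairs,
                                   ClassifyParams(scheme=scheme),
                                   outgroup_ancestral)
            tally = {}
            for p in pairs:
                tally[p.mode] = tally.get(p.mode, 0) + 1
            counts[scheme] = tally
        b, s, e, f = (counts[k] for k in ("binary", "standard", "extended",
                                          "full"))
        assert b.get("SSD", 0) == sum(s.get(m, 0) for m in ("TD", "PD", "DD"))
        assert s.get("DD", 0) == e.get("TRD", 0) + e.get("DD", 0)
        assert e.get("TRD", 0) == f.get("rTRD", 0) + f.get("dTRD", 0)
        assert b.get("SD", 0) == s.get("SD", 0) == e.get("SD", 0)


class TestClassifyGenes:
    def test_hierarchy(self):
        pairs = [DuplicatePair("a", "b", "SD"), DuplicatePair("a", "c", "DD"),
                 DuplicatePair("c", "d", "DD")]
        modes = {g.gene: g.mode
                 for g in classify_genes(pairs, scheme="standard")}
        assert modes == {"a": "SD", "b": "SD", "c": "DD", "d": "DD"}

    def test_rtrd_beats_dtrd(self):
        pairs = [DuplicatePair("a", "b", "dTRD"),
                 DuplicatePair("a", "c", "rTRD")]
        modes = {g.gene: g.mode for g in classify_genes(pairs, scheme="full")}
        assert modes["a"] == "rTRD"

    def test_mode_inconsistent_with_scheme_raises(self):
        with pytest.raises(DupmodeError, match="TRD"):
            classify_genes([DuplicatePair("a", "b", "TRD")], scheme="standard")

    def test_no_gene_below_its_best_pair(self, full_pairs):
        hierarchy = ("SD", "TD", "PD", "rTRD", "dTRD", "DD")
        priority = {m: i for i, m in enumerate(hierarchy)}
        best = {}
        for p in full_pairs:
            for g in (p.gene1, p.gene2):
                best[g] = min(best.get(g, 99), priority[p.mode])
        for cls in classify_genes(full_pairs, scheme="full"):
            assert priority[cls.mode] == best[cls.gene]

    def test_singletons_excluded_but_reported(self, dataset, full_pairs):
        genes = {c.gene for c in classify_genes(full_pairs, scheme="full")}
        lonely = singletons(dataset.query, full_pairs)
        assert genes.isdisjoint(lonely)
        assert len(genes) + len(lonely) == len(dataset.query)


class TestFrequencies:
    def test_counts_and_fractions(self):
        pairs = [DuplicatePair(f"a{i}", f"b{i}", "TD") for i in range(3)]
        pairs.append(DuplicatePair("x", "y", "SD"))
        freq = duplicate_frequencies(pairs, by="pair").set_index("mode")
        assert freq.loc["SD", "n"] == 1 and freq.loc["TD", "n"] == 3
        assert freq.loc["SD", "fraction"] == 0.25
        assert freq["fraction"].sum() == pytest.approx(1.0)

    def test_empty_input_zero_counts(self):
        freq = duplicate_frequencies([], by="pair", scheme="standard")
        assert (freq["n"] == 0).all() and (freq["fraction"] == 0).all()

    def test_gene_level_counts_match_planted_design(self, dataset,
                                                    full_pairs):
        genes = classify_genes(full_pairs, scheme="full")
        freq = duplicate_frequencies(genes, by="gene",
                                     scheme="full").set_index("mode")
        cfg = dataset.config
        # every member of a planted pair is a duplicated gene; SD sources
        # and copies all rank above everything else in the hierarchy
        assert freq.loc["SD", "n"] == 2 * cfg.sd_block_len * cfg.mode_counts["SD"]
        for mode in ("TD", "PD", "rTRD", "dTRD", "DD"):
            assert freq.loc[mode, "n"] == 2 * cfg.mode_counts[mode]


@settings(max_examples=20, deadline=None)
@given(st.randoms(use_true_random=False))
def test_classification_invariant_to_pair_order(rnd):
    index = make_index(30)
    raw = [("g01", "g02"), ("g05", "g09"), ("g03", "g20"), ("g11", "g12"),
           ("g04", "g28"), ("g06", "g16")]
    rnd.shuffle(raw)
    paranome = _paranome(*raw)
    pairs = classify_pairs(paranome, index, {("g01", "g02")})
    labels = {p.key: p.mode for p in pairs}
    assert labels == {
        canonical_pair("g01", "g02"): "SD",
        canonical_pair("g05", "g09"): "PD",
        canonical_pair("g03", "g20"): "DD",
        canonical_pair("g11", "g12"): "TD",
        canonical_pair("g04", "g28"): "DD",
        canonical_pair("g06", "g16"): "PD",
    }
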