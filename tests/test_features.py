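import numpy as np
import pytest

from helpers import slow_factors

from crfref.corpus_io import QueryPair, Thesaurus, make_reference
from crfref.entity_match import find_mentions
from crfref.features import (
    FACTOR_NAMES,
    CorpusStats,
    assemble,
    compute_corpus_stats,
    conclusiveness_factors,
    crfref_features,
    focus_factors,
    richness_factors,
)
from crfref.synthetic import SimConfig, generate_corpus


def factors_for(ref, pair, gthes, dthes, stats, variant="full"):
    gmi = find_mentions(ref, gthes)
    dmi = find_mentions(ref, dthes)
    return assemble(ref, pair, gmi, dmi, stats, variant)


@pytest.fixture
def stats():
    return CorpusStats(n_refs=10, avg_len=10.0, df={"HBB": 4, "scd": 6})


def test_gene_as_final_token_at_avg_length(gene_thesaurus, disease_thesaurus, stats):
    """|r| = AvgLen and g ending the body give length = ending = 1."""
    ref = make_reference("r", "", sentences=["w1 w2 w3 w4 w5 w6 w7 w8 w9 HBB"])
    pair = QueryPair("p", "HBB", "scd")
    gmi = find_mentions(ref, gene_thesaurus)
    dmi = find_mentions(ref, disease_thesaurus)
    f = conclusiveness_factors(ref, pair, gmi, dmi, stats)
    assert f[0] == 1.0
    assert f[5] == 1.0
    assert f[1] == pytest.approx(1 / 3)


def test_absent_gene_gives_zero_factors(gene_thesaurus, disease_thesaurus, stats, pair):
    ref = make_reference("r", "", sentences=["sickle cell disease only"])
    f = factors_for(ref, pair, gene_thesaurus, disease_thesaurus, stats)
    assert f[1] == f[3] == f[5] == 0.0


def test_hand_computed_disease_factors(gene_thesaurus, stats):
    """|r| = 10, d's last match ends at 1-based token 5, TF(d) = 2."""
    thes = Thesaurus("disease", {"d": (("dz",),)})
    ref = make_reference("r", "", sentences=["dz w1 w2 w3 dz w5 w6 w7 w8 w9"])
    pair = QueryPair("p", "HBB", "d")
    gmi = find_mentions(ref, gene_thesaurus)
    dmi = find_mentions(ref, thes)
    f = conclusiveness_factors(ref, pair, gmi, dmi, stats)
    assert len(ref) == 10
    assert f[6] == pytest.approx(0.5)
    assert f[2] == pytest.approx(2 / 3)


@pytest.mark.parametrize("n_other,expected", [(0, 0.0), (1, 0.5), (3, 0.75)])
def test_richness_squash(n_other, expected, disease_thesaurus):
    entries = {"g0": (("g0x",),)}
    entries.update({f"g{i+1}": ((f"d{i}x",),) for i in range(n_other)})
    thes = Thesaurus("gene", entries)
    body = "g0x " + " ".join(f"d{i}x" for i in range(n_other)) + " filler"
    ref = make_reference("r", "", sentences=[body])
    pair = QueryPair("p", "g0", "scd")
    f = richness_factors(ref, pair, find_mentions(ref, thes), find_mentions(ref, disease_thesaurus))
    assert f[0] == pytest.approx(expected)


def test_focus_zero_without_distractors(gene_thesaurus, disease_thesaurus, pair):
    ref = make_reference("r", "HBB and sickle cell disease")
    f = focus_factors(
        ref, pair, find_mentions(ref, gene_thesaurus), find_mentions(ref, disease_thesaurus)
    )
    assert np.all(f == 0.0)


def test_focus_ending_is_max_over_distractors(disease_thesaurus, pair):
    thes = Thesaurus(
        "gene", {"HBB": (("HBB",),), "A": (("ax",),), "B": (("bx",),)}
    )
    # A's last match ends mid-body, B's at the final token
    ref = make_reference("r", "", sentences=["HBB ax w1 w2 ax w5 w6 w7 w8 bx"])
    f = focus_factors(
        ref, pair, find_mentions(ref, thes), find_mentions(ref, disease_thesaurus)
    )
    assert f[2] == pytest.approx(1.0)


def test_distractor_in_title_sets_flag(disease_thesaurus, pair):
    thes = Thesaurus("gene", {"HBB": (("HBB",),), "A": (("ax",),)})
    ref = make_reference("r", "ax in title", sentences=["HBB here"])
    f = focus_factors(
        ref, pair, find_mentions(ref, thes), find_mentions(ref, disease_thesaurus)
    )
    assert f[0] == 1.0 and f[1] == 0.0


class TestAssemble:
    def test_variant_lengths(self, sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats):
        args = (sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats)
        assert len(crfref_features(*args, variant="conclusiveness")) == 7
        assert len(crfref_features(*args, variant="conclusiveness_richness")) == 9
        assert len(crfref_features(*args, variant="full")) == 13
        assert len(FACTOR_NAMES) == 13

    def test_prefix_property(self, sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats):
        args = (sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats)
        full = crfref_features(*args, variant="full")
        cr = crfref_features(*args, variant="conclusiveness_richness")
        c = crfref_features(*args, variant="conclusiveness")
        assert np.array_equal(full[:9], cr)
        assert np.array_equal(cr[:7], c)

    def test_full_is_group_concatenation(self, sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats):
        gmi = find_mentions(sickle_ref, gene_thesaurus)
        dmi = find_mentions(sickle_ref, disease_thesaurus)
        full = assemble(sickle_ref, pair, gmi, dmi, stats, "full")
        expected = np.concatenate(
            [
                conclusiveness_factors(sickle_ref, pair, gmi, dmi, stats),
                richness_factors(sickle_ref, pair, gmi, dmi),
                focus_factors(sickle_ref, pair, gmi, dmi),
            ]
        )
        assert np.array_equal(full, expected)

    def test_unknown_variant_errors(self, sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats):
        with pytest.raises(ValueError, match="variant"):
            crfref_features(
                sickle_ref, pair, gene_thesaurus, disease_thesaurus, stats, "bogus"
            )


def test_all_factors_in_unit_interval_on_synthetic_corpus():
    corpus = generate_corpus(SimConfig(n_pairs=12, seed=11))
    stats = compute_corpus_stats(
        list(corpus.references), corpus.gene_thesaurus, corpus.disease_thesaurus
    )
    ref_map = corpus.reference_map()
    for p in corpus.pairs:
        for rid in corpus.candidates[p.pair_id]:
            f = crfref_features(
                ref_map[rid], p, corpus.gene_thesaurus, corpus.disease_thesaurus, stats
            )
            assert np.all(f >= 0.0) and np.all(f <= 1.0)
            assert f[3] in (0.0, 1.0) and f[4] in (0.0, 1.0)


def test_later_last_mention_does_not_lower_ending_score(stats):
    """Moving the final g-mention later (|r| fixed) is monotone for factor 6."""
    thes = Thesaurus("gene", {"g": (("gx",),)})
    dthes = Thesaurus("disease", {"d": (("dx",),)})
    pair = QueryPair("p", "g", "d")
    prev = -1.0
    for pos in range(10):
        toks = ["w"] * 10
        toks[pos] = "gx"
        ref = make_reference("r", "", sentences=[" ".join(toks)])
        f = factors_for(ref, pair, thes, dthes, stats)
        assert f[5] >= prev
        prev = f[5]


def test_extra_distractor_never_decreases_richness_or_focus(stats):
    thes = Thesaurus(
        "gene", {"g": (("gx",),), **{f"o{i}": ((f"ox{i}",),) for i in range(5)}}
    )
    dthes = Thesaurus("disease", {"d": (("dx",),)})
    pair = QueryPair("p", "g", "d")
    prev = None
    for k in range(5):
        toks = ["gx"] + [f"ox{i}" for i in range(k)] + ["w"] * (9 - k)
        ref = make_reference("r", "", sentences=[" ".join(toks)])
        f = factors_for(ref, pair, thes, dthes, stats)
        if prev is not None:
            assert f[7] >= prev[7]
            assert f[11] >= prev[11]
        prev = f


def test_factors_match_slow_reimplementation(gene_thesaurus, disease_thesaurus, pair):
    from conftest import random_reference

    rng = np.random.default_rng(3)
    refs = [
        random_reference(rng, f"r{i}", (gene_thesaurus, disease_thesaurus))
        for i in range(40)
    ]
    stats = compute_corpus_stats(refs, gene_thesaurus, disease_thesaurus)
    for ref in refs:
        fast = crfref_features(ref, pair, gene_thesaurus, disease_thesaurus, stats)
        slow = slow_factors(ref, pair, gene_thesaurus, disease_thesaurus, stats.avg_len)
        np.testing.assert_allclose(fast, slow, atol=1e-12)


def test_degenerate_reference_rejected(gene_thesaurus, disease_thesaurus, pair, stats):
    with pytest.raises(ValueError):
        make_reference("r", "", sentences=[])


def test_corpus_stats_df_counts_presence_not_frequency(gene_thesaurus, disease_thesaurus):
    r1 = make_reference("r1", "HBB HBB HBB")
    r2 = make_reference("r2", "stroke and HBB")
    r3 = make_reference("r3", "nothing")
    stats = compute_corpus_stats([r1, r2, r3], gene_thesaurus, disease_thesaurus)
    assert stats.n_refs == 3
    assert stats.df_of("HBB") == 2
    assert stats.df_of("stroke") == 1
    assert stats.df_of("scd") == 0
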