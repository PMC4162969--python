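import math

import numpy as np
import pytest

from helpers import brute_bm25, brute_proximity_boost, brute_vsm

from crfref.baselines import (
    Bm25Params,
    posfreq_features,
    proximity_adjust_tf,
    proximity_bm25_score,
    bm25_score,
    vsm_score,
)
from crfref.corpus_io import QueryPair, Thesaurus, make_reference
from crfref.entity_match import find_mentions
from crfref.features import CorpusStats, compute_corpus_stats


@pytest.fixture
def toy():
    """Three-document corpus with known mention counts."""
    gthes = Thesaurus("gene", {"g": (("gx",),)})
    dthes = Thesaurus("disease", {"d": (("dx",),)})
    pair = QueryPair("p", "g", "d")
    refs = [
        make_reference("r1", "gx w1", sentences=["dx w2 w3 gx"]),
        make_reference("r2", "", sentences=["w1 w2 gx w3 w4 w5"]),
        make_reference("r3", "w1 w2", sentences=["w3 w4"]),
    ]
    stats = compute_corpus_stats(refs, gthes, dthes)
    return gthes, dthes, pair, refs, stats


def mentions(ref, gthes, dthes):
    return find_mentions(ref, gthes), find_mentions(ref, dthes)


class TestBm25:
    def test_zero_when_neither_entity_present(self, toy):
        gthes, dthes, pair, refs, stats = toy
        assert bm25_score(refs[2], pair, *mentions(refs[2], gthes, dthes), stats) == 0.0

    def test_matches_independent_formula(self, toy):
        gthes, dthes, pair, refs, stats = toy
        for ref in refs:
            gmi, dmi = mentions(ref, gthes, dthes)
            expected = brute_bm25(
                gmi.tf("g"), stats.n_refs, stats.df_of("g"), len(ref), stats.avg_len
            ) + brute_bm25(
                dmi.tf("d"), stats.n_refs, stats.df_of("d"), len(ref), stats.avg_len
            )
            got = bm25_score(ref, pair, gmi, dmi, stats)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_saturating_in_tf(self, toy):
        gthes, dthes, pair, refs, stats = toy
        ref = refs[0]
        gmi, dmi = mentions(ref, gthes, dthes)
        params = Bm25Params()
        # the disease term has positive idf (df=1 of 3)
        idf = math.log((stats.n_refs - stats.df_of("d") + 0.5) / (stats.df_of("d") + 0.5))
        assert idf > 0
        prev = -1.0
        for tf in range(1, 30):
            s = bm25_score(ref, pair, gmi, dmi, stats, params, tf_override=(0.0, tf))
            assert s > prev
            assert s < idf * (params.k1 + 1)
            prev = s

    def test_idf_floored_at_zero(self):
        stats = CorpusStats(2, 5.0, {"g": 2})  # entity in every doc -> negative raw idf
        gthes = Thesaurus("gene", {"g": (("gx",),)})
        dthes = Thesaurus("disease", {"d": (("dx",),)})
        ref = make_reference("r", "gx w1 w2 w3 w4")
        pair = QueryPair("p", "g", "d")
        assert bm25_score(ref, pair, *mentions(ref, gthes, dthes), stats) == 0.0

    def test_empty_reference_errors(self, toy):
        gthes, dthes, pair, refs, stats = toy
        with pytest.raises(ValueError):
            make_reference("r0", "", sentences=[])

    def test_param_validation(self):
        with pytest.raises(ValueError):
            Bm25Params(k1=0)
        with pytest.raises(ValueError):
            Bm25Params(b=1.5)


class TestVsm:
    def test_zero_when_absent(self, toy):
        gthes, dthes, pair, refs, stats = toy
        assert vsm_score(refs[2], pair, *mentions(refs[2], gthes, dthes), stats) == 0.0

    def test_matches_independent_formula(self, toy):
        gthes, dthes, pair, refs, stats = toy
        for ref in refs:
            gmi, dmi = mentions(ref, gthes, dthes)
            expected = brute_vsm(gmi.tf("g"), stats.n_refs, stats.df_of("g"), len(ref))
            expected += brute_vsm(dmi.tf("d"), stats.n_refs, stats.df_of("d"), len(ref))
            assert vsm_score(ref, pair, gmi, dmi, stats) == pytest.approx(
                expected, abs=1e-9
            )

    def test_doubling_length_divides_by_sqrt2(self, toy):
        gthes, dthes, pair, refs, stats = toy
        short = make_reference("s", "gx w1 w2 w3")
        long = make_reference("l", "gx " + " ".join(f"v{i}" for i in range(7)))
        s_short = vsm_score(short, pair, *mentions(short, gthes, dthes), stats)
        s_long = vsm_score(long, pair, *mentions(long, gthes, dthes), stats)
        assert s_long == pytest.approx(s_short / math.sqrt(2))


class TestProximity:
    def test_no_increment_when_other_term_absent(self, toy):
        gthes, dthes, pair, refs, stats = toy
        ref = refs[1]  # g only
        gmi, dmi = mentions(ref, gthes, dthes)
        tfg, tfd = proximity_adjust_tf(ref, pair, gmi, dmi)
        assert tfg == gmi.tf("g")
        assert tfd == 0.0

    def test_colocated_pair_increments_by_one(self):
        # same start position for both terms via a shared single-token alias
        gthes = Thesaurus("gene", {"g": (("gx",),)})
        dthes = Thesaurus("disease", {"d": (("gx",),)})  # shared alias -> same starts
        ref = make_reference("r", "gx w1 w2")
        pair = QueryPair("p", "g", "d")
        gmi, dmi = find_mentions(ref, gthes), find_mentions(ref, dthes)
        tfg, tfd = proximity_adjust_tf(ref, pair, gmi, dmi, sigma=5.0)
        assert tfg == pytest.approx(1.0 + 1.0)
        assert tfd == pytest.approx(1.0 + 1.0)

    def test_matches_brute_force_double_sum(self, toy):
        gthes, dthes, pair, refs, stats = toy
        rng = np.random.default_rng(5)
        for trial in range(20):
            toks = []
            for _ in range(int(rng.integers(10, 40))):
                u = rng.random()
                toks.append("gx" if u < 0.2 else "dx" if u < 0.4 else f"w{int(rng.integers(9))}")
            ref = make_reference("r", "", sentences=[" ".join(toks)])
            gmi, dmi = mentions(ref, gthes, dthes)
            sigma = float(rng.uniform(1, 30))
            tfg, tfd = proximity_adjust_tf(ref, pair, gmi, dmi, sigma=sigma)
            boost = brute_proximity_boost(
                [m.start for m in gmi.matches("g")],
                [m.start for m in dmi.matches("d")],
                sigma,
            )
            assert tfg == pytest.approx(gmi.tf("g") + boost, abs=1e-9)
            assert tfd == pytest.approx(dmi.tf("d") + boost, abs=1e-9)
            assert tfg >= gmi.tf("g") and tfd >= dmi.tf("d")

    def test_proximity_feeds_bm25(self, toy):
        gthes, dthes, pair, refs, stats = toy
        ref = refs[0]
        gmi, dmi = mentions(ref, gthes, dthes)
        plain = bm25_score(ref, pair, gmi, dmi, stats)
        boosted = proximity_bm25_score(ref, pair, gmi, dmi, stats, sigma=10.0)
        assert boosted > plain


class TestPosFreq:
    def make(self, title, sents):
        return make_reference("r", title, sentences=sents)

    @pytest.fixture
    def thesauri(self):
        return (
            Thesaurus("gene", {"g": (("gx",),)}),
            Thesaurus("disease", {"d": (("dx",),)}),
        )

    def flags(self, ref, thesauri):
        gthes, dthes = thesauri
        pair = QueryPair("p", "g", "d")
        return posfreq_features(ref, pair, find_mentions(ref, gthes), find_mentions(ref, dthes))

    def test_title_only_gene(self, thesauri):
        ref = self.make("gx in title", ["w1 w2 w3"])
        f = self.flags(ref, thesauri)
        assert f[0] == 1.0 and f[2] == 0.0 and f[6] == 0.0

    def test_single_sentence_is_both_first_and_last(self, thesauri):
        ref = self.make("t", ["dx w1 w2"])
        f = self.flags(ref, thesauri)
        assert f[3] == 1.0 and f[5] == 1.0

    def test_three_times_in_middle_sentence(self, thesauri):
        ref = self.make("t", ["w1 w2", "gx gx gx w3", "w4 w5"])
        f = self.flags(ref, thesauri)
        assert f[6] == 1.0
        assert f[2] == 0.0 and f[4] == 0.0

    def test_title_mentions_do_not_count_toward_tf3(self, thesauri):
        ref = self.make("gx gx gx", ["w1 gx w2"])
        f = self.flags(ref, thesauri)
        assert f[6] == 0.0

    def test_zero_vector_without_entities(self, thesauri):
        ref = self.make("w1 w2", ["w3 w4"])
        assert np.all(self.flags(ref, thesauri) == 0.0)

    def test_no_sentences_zeroes_sentence_flags(self, thesauri):
        ref = self.make("gx dx", [])
        f = self.flags(ref, thesauri)
        assert f[0] == 1.0 and f[1] == 1.0
        assert np.all(f[2:6] == 0.0)
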