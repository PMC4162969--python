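"""Comparison rankers: BM25, a tf-idf vector-space scorer, a
proximity-boosted BM25, and the position-and-frequency feature set
(PosFreq).

The query is always a gene-disease pair with alias folding: every alias
of g counts as g and every alias of d counts as d, so the "term
frequency" of a query term is its mention count from the dictionary
matcher.

The proximity ranker is a generic stand-in for published proximity
enhancers: each co-occurring (gene, disease) mention pair adds a Gaussian
kernel of the token distance to both term frequencies, so nearby mentions
raise the BM25 score and distant ones add almost nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corpus_io import QueryPair, Reference
from .entity_match import MentionIndex
from .features import CorpusStats

__all__ = [
    "Bm25Params",
    "POSFREQ_NAMES",
    "bm25_score",
    "vsm_score",
    "proximity_adjust_tf",
    "proximity_bm25_score",
    "posfreq_features",
]


@dataclass(frozen=True)
class Bm25Params:
    """Okapi constants; defaults k1=2, b=0.75."""

    k1: float = 2.0
    b: float = 0.75

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError("k1 must be positive")
        if not 0 <= self.b <= 1:
            raise ValueError("b must lie in [0, 1]")


POSFREQ_NAMES = (
    "g_in_title",
    "d_in_title",
    "g_first_sentence",
    "d_last_sentence",
    "g_last_sentence",
    "d_first_sentence",
    "g_tf_ge3",
    "d_tf_ge3",
)


def _idf_bm25(n_refs: int, df: int) -> float:
    # floored at 0 so a very common entity cannot push the score negative
    return max(0.0, math.log((n_refs - df + 0.5) / (df + 0.5)))


def bm25_score(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
    stats: CorpusStats,
    params: Bm25Params = Bm25Params(),
    tf_override: tuple[float, float] | None = None,
) -> float:
    """Okapi BM25 over the two query terms g and d.

    score = sum_t idf(t) * TF * (k1+1) / (TF + k1 * (1 - b + b*|r|/avgrl))
    with idf(t) = max(0, ln((N - n + 0.5) / (n + 0.5))).

    ``tf_override`` substitutes adjusted term frequencies (used by the
    proximity ranker) for the raw mention counts.
    """
    n = len(ref)
    if n == 0:
        raise ValueError(f"reference {ref.ref_id!r} has no tokens")
    if tf_override is not None:
        tfs = tf_override
    else:
        tfs = (
            float(gene_mentions.tf(pair.gene_id)),
            float(disease_mentions.tf(pair.disease_id)),
        )
    norm = params.k1 * (1 - params.b + params.b * n / stats.avg_len)
    score = 0.0
    for eid, tf in zip((pair.gene_id, pair.disease_id), tfs):
        if tf <= 0:
            continue
        idf = _idf_bm25(stats.n_refs, stats.df_of(eid))
        score += idf * tf * (params.k1 + 1) / (tf + norm)
    return score


def vsm_score(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
    stats: CorpusStats,
) -> float:
    """Classic practical tf-idf cosine score over the two query terms.

    score = sum_t sqrt(TF(t, r)) * idf(t)^2 / sqrt(|r|)
    with idf(t) = 1 + ln(N / (n + 1)).
    """
    n = len(ref)
    if n == 0:
        raise ValueError(f"reference {ref.ref_id!r} has no tokens")
    score = 0.0
    for eid, mi in ((pair.gene_id, gene_mentions), (pair.disease_id, disease_mentions)):
        tf = mi.tf(eid)
        if tf == 0:
            continue
        idf = 1.0 + math.log(stats.n_refs / (stats.df_of(eid) + 1.0))
        score += math.sqrt(tf) * idf * idf
    return score / math.sqrt(n)


def proximity_adjust_tf(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
    sigma: float = 25.0,
) -> tuple[float, float]:
    """Raise each query term's TF by the proximity of the other term.

    Every (gene occurrence, disease occurrence) pair contributes
    exp(-dist^2 / (2 sigma^2)) — dist being the token distance between
    match starts — to both adjusted frequencies, so co-located mentions
    add a full extra count and far-apart ones almost nothing.  The
    increment is never negative, so TF' >= TF.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    g_pos = [m.start for m in gene_mentions.matches(pair.gene_id)]
    d_pos = [m.start for m in disease_mentions.matches(pair.disease_id)]
    boost = 0.0
    for i in g_pos:
        for j in d_pos:
            boost += math.exp(-((i - j) ** 2) / (2.0 * sigma * sigma))
    return (len(g_pos) + boost, len(d_pos) + boost)


def proximity_bm25_score(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
    stats: CorpusStats,
    params: Bm25Params = Bm25Params(),
    sigma: float = 25.0,
) -> float:
    """BM25 fed with the proximity-adjusted term frequencies."""
    tfs = proximity_adjust_tf(ref, pair, gene_mentions, disease_mentions, sigma)
    return bm25_score(
        ref, pair, gene_mentions, disease_mentions, stats, params, tf_override=tfs
    )


def _in_sentence(mi: MentionIndex, eid: str, ref: Reference, bounds: tuple[int, int]) -> bool:
    lo, hi = bounds
    off = len(ref.title_tokens)
    return any(
        not m.in_title and lo <= m.start - off < hi for m in mi.matches(eid)
    )


def posfreq_features(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
) -> np.ndarray:
    """The eight position/frequency indicator features.

    In order: g in title, d in title, g in first sentence, d in last
    sentence, g in last sentence, d in first sentence, g at least three
    times in the abstract, d at least three times in the abstract.
    Sentence flags are 0 when the abstract has no sentences.
    """
    g, d = pair.gene_id, pair.disease_id
    gmi, dmi = gene_mentions, disease_mentions
    out = np.zeros(8)
    out[0] = 1.0 if gmi.in_title(g) else 0.0
    out[1] = 1.0 if dmi.in_title(d) else 0.0
    if ref.sentence_bounds:
        first = ref.sentence_bounds[0]
        last = ref.sentence_bounds[-1]
        out[2] = 1.0 if _in_sentence(gmi, g, ref, first) else 0.0
        out[3] = 1.0 if _in_sentence(dmi, d, ref, last) else 0.0
        out[4] = 1.0 if _in_sentence(gmi, g, ref, last) else 0.0
        out[5] = 1.0 if _in_sentence(dmi, d, ref, first) else 0.0
    out[6] = 1.0 if gmi.tf(g, title=False) >= 3 else 0.0
    out[7] = 1.0 if dmi.tf(d, title=False) >= 3 else 0.0
    return out
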