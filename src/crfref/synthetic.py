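"""Synthetic corpora with planted conclusiveness / richness / focus
structure.

Real evaluation corpora for curation triage are built from literature
databases and curator judgments that cannot be shipped; this module
emulates their load-bearing properties instead.  Each query pair gets a
batch of candidate abstracts with controlled entity placement — the gene
and disease are always mentioned (so every candidate survives
candidate filtering), sometimes in the title, sometimes in the final
sentence, with Poisson mention counts — plus distractor genes and
diseases planted in the body, title and ending.  Relevance is defined
*directly on the factor space*: each candidate's own 13 factors f enter a
logistic model P(target) = sigmoid(beta . f + intercept + pair offset),
labels are drawn (or thresholded, for separable data) and flipped at a
noise rate.  Planted effects are therefore provable properties of the
generator: a ranker using the informative factor groups is better by
construction, and per-pair target fractions vary widely across pairs
because of the per-pair intercept offset.

Filler tokens come from a closed vocabulary disjoint from every alias,
so no accidental entity matches occur.  A fixed seed reproduces the
corpus byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import corpus_io
from .corpus_io import QueryPair, Reference, Thesaurus
from .entity_match import find_mentions
from .features import assemble, compute_corpus_stats

__all__ = [
    "SimConfig",
    "Corpus",
    "DEFAULT_BETA",
    "ABLATION_BETA",
    "generate_thesauri",
    "generate_corpus",
    "ablation_config",
    "recovery_config",
    "write_corpus",
    "read_corpus",
]

#: Default planted coefficients over the 13 factors: positive weight on the
#: query pair's conclusiveness and richness, negative weight on distractor
#: conclusiveness (focus dilution).
DEFAULT_BETA = (
    0.5, 1.2, 1.2, 1.5, 1.5, 2.0, 2.0,  # conclusiveness 1-7
    1.2, 1.2,                            # richness 8-9
    -1.5, -1.5, -2.0, -2.0,              # focus 10-13
)

#: Coefficients concentrating signal on the richness and focus factors,
#: for ablation studies of the factor groups.
ABLATION_BETA = (
    0.1, 0.2, 0.2, 0.3, 0.3, 0.4, 0.4,
    2.5, 2.5,
    -5.0, -5.0, -6.0, -6.0,
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_pairs: int = 100
    candidates_min: int = 10
    candidates_max: int = 30
    n_genes: int = 40
    n_diseases: int = 40
    alias_ambiguity: float = 0.0
    p_multi_token_alias: float = 0.5
    title_len: int = 8
    n_sentences: int = 5
    sentence_len: int = 18
    # placement probabilities for the query entities
    p_gene_title: float = 0.35
    p_disease_title: float = 0.45
    p_gene_ending: float = 0.4
    p_disease_ending: float = 0.4
    mention_lambda: float = 1.0       # extra mentions beyond the guaranteed one
    distractor_lambda: float = 1.2    # distractor entities per type
    p_distractor_title: float = 0.15
    p_distractor_ending: float = 0.25
    # planted relevance model
    beta: tuple[float, ...] = DEFAULT_BETA
    intercept: float = -6.5
    intercept_jitter: float = 3.0     # per-pair offset ~ U(-jitter, +jitter)
    label_noise: float = 0.05
    deterministic_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "candidates_min", "n_genes", "n_diseases",
                     "title_len", "n_sentences", "sentence_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.candidates_max < self.candidates_min:
            raise ValueError("candidates_max < candidates_min")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if len(self.beta) != 13:
            raise ValueError("beta must have 13 coefficients")
        if self.n_genes < 2 or self.n_diseases < 2:
            raise ValueError("thesauri need at least 2 entities")


@dataclass(frozen=True)
class Corpus:
    """A complete simulated study: corpus, thesauri, queries, judgments."""

    references: tuple[Reference, ...]
    pairs: tuple[QueryPair, ...]
    candidates: Mapping[str, Sequence[str]]
    qrels: Mapping[str, frozenset[str]]
    gene_thesaurus: Thesaurus
    disease_thesaurus: Thesaurus
    config: SimConfig | None = None

    def reference_map(self) -> dict[str, Reference]:
        return {r.ref_id: r for r in self.references}


def ablation_config(**overrides) -> SimConfig:
    """Study conditions for factor-group ablations.

    The planted signal is concentrated on the richness and focus factors:
    distractor placement is frequent enough that those factors vary
    strongly within pairs, their coefficients dominate the weak
    conclusiveness ones, and the intercept centres the relevance
    probability so that genuine targets (not noise flips) carry the
    labels.  Designed against the generating model itself: the true-beta
    scorer beats its conclusiveness-only restriction by a wide MAP margin
    under these conditions, so a correct learner must reproduce the
    full >= conclusiveness+richness >= conclusiveness ordering.
    """
    base = SimConfig(
        n_pairs=300,
        beta=ABLATION_BETA,
        label_noise=0.1,
        distractor_lambda=2.0,
        p_distractor_ending=0.35,
        p_distractor_title=0.2,
        intercept=6.3,
        intercept_jitter=1.0,
    )
    return replace(base, **overrides)


def recovery_config(**overrides) -> SimConfig:
    """Noise-free, threshold-labelled conditions for weight recovery."""
    base = SimConfig(
        n_pairs=200,
        candidates_min=20,
        candidates_max=20,
        label_noise=0.0,
        deterministic_labels=True,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# thesauri

def _alias_word(prefix: str, i: int, j: int) -> str:
    return f"{prefix}{i}w{j}"


def generate_thesauri(cfg: SimConfig) -> tuple[Thesaurus, Thesaurus]:
    """Synthetic gene and disease thesauri with 1-3 aliases per entity.

    Every entity gets an all-uppercase symbol alias (normalization keeps
    it verbatim) and, with probability ``p_multi_token_alias``, one
    multi-token lowercase alias.  Aliases are unique across entities
    unless ``alias_ambiguity`` > 0, in which case an entity shares its
    symbol with the previous entity at that rate.
    """
    rng = np.random.default_rng([1, cfg.seed])

    def build(n: int, sym: str, word: str) -> dict[str, tuple[tuple[str, ...], ...]]:
        entries: dict[str, tuple[tuple[str, ...], ...]] = {}
        ids = [f"{word}{i:04d}" for i in range(n)]
        for i, eid in enumerate(ids):
            aliases: list[tuple[str, ...]] = [(f"{sym}{i}X",)]
            if rng.random() < cfg.p_multi_token_alias:
                k = int(rng.integers(2, 4))
                aliases.append(tuple(_alias_word(word, i, j) for j in range(k)))
            if rng.random() < 0.5:
                aliases.append((_alias_word(word, i, 9),))
            if i > 0 and rng.random() < cfg.alias_ambiguity:
                prev = entries[ids[i - 1]]
                aliases.append(prev[0])
            entries[eid] = tuple(aliases)
        return entries

    genes = Thesaurus("gene", build(cfg.n_genes, "GS", "gn"))
    diseases = Thesaurus("disease", build(cfg.n_diseases, "DS", "ds"))
    return genes, diseases


# ---------------------------------------------------------------------------
# corpus

_FILLER_VOCAB = tuple(f"txt{i:03d}" for i in range(400))


class _Doc:
    """A document under construction: title + sentences as cells of tokens."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.rng = rng
        self.title = [
            [str(rng.choice(_FILLER_VOCAB))] for _ in range(cfg.title_len)
        ]
        self.sentences = [
            [[str(rng.choice(_FILLER_VOCAB))] for _ in range(cfg.sentence_len)]
            for _ in range(cfg.n_sentences)
        ]
        self._free_title = list(range(cfg.title_len))
        self._free = [
            (s, c) for s in range(cfg.n_sentences) for c in range(cfg.sentence_len)
        ]

    def plant_title(self, alias: Sequence[str]) -> bool:
        if not self._free_title:
            return False
        k = self._free_title.pop(int(self.rng.integers(len(self._free_title))))
        self.title[k] = list(alias)
        return True

    def plant_body(self, alias: Sequence[str], sentence: int | None = None) -> bool:
        pool = (
            [i for i, (s, _) in enumerate(self._free) if s == sentence]
            if sentence is not None
            else list(range(len(self._free)))
        )
        if not pool:
            return False
        idx = pool[int(self.rng.integers(len(pool)))]
        s, c = self._free.pop(idx)
        self.sentences[s][c] = list(alias)
        return True

    def build(self, ref_id: str) -> Reference:
        title = [tok for cell in self.title for tok in cell]
        sents = [
            " ".join(tok for cell in sent for tok in cell)
            for sent in self.sentences
        ]
        return corpus_io.make_reference(
            ref_id, " ".join(title), sentences=sents
        )


def _pick_alias(aliases: Sequence[tuple[str, ...]], rng: np.random.Generator):
    return aliases[int(rng.integers(len(aliases)))]


def generate_corpus(
    cfg: SimConfig,
    thesauri: tuple[Thesaurus, Thesaurus] | None = None,
) -> Corpus:
    """Generate references, query pairs and qrels under ``cfg``.

    Candidates are generated per pair and always mention both query
    entities.  Labels come from the planted logistic (or threshold) model
    on each candidate's own factors, evaluated with corpus-wide statistics.
    """
    if thesauri is None:
        thesauri = generate_thesauri(cfg)
    gene_thes, disease_thes = thesauri
    rng = np.random.default_rng([2, cfg.seed])

    gene_ids = sorted(gene_thes.entries)
    disease_ids = sorted(disease_thes.entries)

    pairs: list[QueryPair] = []
    candidates: dict[str, list[str]] = {}
    refs: list[Reference] = []
    pair_offsets: dict[str, float] = {}
    ref_counter = 0

    for p in range(cfg.n_pairs):
        pair = QueryPair(
            f"p{p:04d}",
            gene_ids[int(rng.integers(len(gene_ids)))],
            disease_ids[int(rng.integers(len(disease_ids)))],
        )
        pairs.append(pair)
        pair_offsets[pair.pair_id] = float(
            rng.uniform(-cfg.intercept_jitter, cfg.intercept_jitter)
        )
        n_cand = int(rng.integers(cfg.candidates_min, cfg.candidates_max + 1))
        cand_ids: list[str] = []
        for _ in range(n_cand):
            ref_id = f"r{ref_counter:06d}"
            ref_counter += 1
            doc = _Doc(cfg, rng)
            g_aliases = gene_thes.entries[pair.gene_id]
            d_aliases = disease_thes.entries[pair.disease_id]

            # query entities: guaranteed body mention + optional placements
            doc.plant_body(_pick_alias(g_aliases, rng))
            doc.plant_body(_pick_alias(d_aliases, rng))
            if rng.random() < cfg.p_gene_title:
                doc.plant_title(_pick_alias(g_aliases, rng))
            if rng.random() < cfg.p_disease_title:
                doc.plant_title(_pick_alias(d_aliases, rng))
            if rng.random() < cfg.p_gene_ending:
                doc.plant_body(_pick_alias(g_aliases, rng), cfg.n_sentences - 1)
            if rng.random() < cfg.p_disease_ending:
                doc.plant_body(_pick_alias(d_aliases, rng), cfg.n_sentences - 1)
            for _ in range(int(rng.poisson(cfg.mention_lambda))):
                doc.plant_body(_pick_alias(g_aliases, rng))
            for _ in range(int(rng.poisson(cfg.mention_lambda))):
                doc.plant_body(_pick_alias(d_aliases, rng))

            # distractor entities
            for ids, thes, query_eid in (
                (gene_ids, gene_thes, pair.gene_id),
                (disease_ids, disease_thes, pair.disease_id),
            ):
                n_dis = int(rng.poisson(cfg.distractor_lambda))
                pool = [e for e in ids if e != query_eid]
                for e_idx in rng.choice(len(pool), size=min(n_dis, len(pool)), replace=False):
                    eid = pool[int(e_idx)]
                    aliases = thes.entries[eid]
                    doc.plant_body(_pick_alias(aliases, rng))
                    if rng.random() < cfg.p_distractor_title:
                        doc.plant_title(_pick_alias(aliases, rng))
                    if rng.random() < cfg.p_distractor_ending:
                        doc.plant_body(
                            _pick_alias(aliases, rng), cfg.n_sentences - 1
                        )

            refs.append(doc.build(ref_id))
            cand_ids.append(ref_id)
        candidates[pair.pair_id] = cand_ids

    # planted relevance from each candidate's own factors
    mentions = {
        r.ref_id: (find_mentions(r, gene_thes), find_mentions(r, disease_thes))
        for r in refs
    }
    stats = compute_corpus_stats(refs, mentions=mentions)
    beta = np.asarray(cfg.beta)
    ref_map = {r.ref_id: r for r in refs}
    label_rng = np.random.default_rng([3, cfg.seed])
    qrels: dict[str, frozenset[str]] = {}
    for pair in pairs:
        targets: set[str] = set()
        for ref_id in candidates[pair.pair_id]:
            ref = ref_map[ref_id]
            gmi, dmi = mentions[ref_id]
            f = assemble(ref, pair, gmi, dmi, stats, "full")
            score = float(beta @ f) + cfg.intercept + pair_offsets[pair.pair_id]
            if cfg.deterministic_labels:
                y = score > 0
            else:
                y = label_rng.random() < expit(score)
            if cfg.label_noise > 0 and label_rng.random() < cfg.label_noise:
                y = not y
            if y:
                targets.add(ref_id)
        qrels[pair.pair_id] = frozenset(targets)

    return Corpus(
        references=tuple(refs),
        pairs=tuple(pairs),
        candidates=candidates,
        qrels=qrels,
        gene_thesaurus=gene_thes,
        disease_thesaurus=disease_thes,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# disk round-trip (the corpus_io dialects)

def write_corpus(directory: str | Path, corpus: Corpus) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    corpus_io.write_references(directory / "references.jsonl", corpus.references)
    corpus_io.write_thesaurus(directory / "gene_thesaurus.tsv", corpus.gene_thesaurus)
    corpus_io.write_thesaurus(
        directory / "disease_thesaurus.tsv", corpus.disease_thesaurus
    )
    corpus_io.write_pairs(directory / "pairs.tsv", corpus.pairs)
    corpus_io.write_candidates(directory / "candidates.tsv", corpus.candidates)
    corpus_io.write_qrels(
        directory / "qrels.tsv",
        {p: set(t) for p, t in corpus.qrels.items()},
        candidates=corpus.candidates,
    )


def read_corpus(directory: str | Path) -> Corpus:
    directory = Path(directory)
    refs = corpus_io.read_references(directory / "references.jsonl")
    qrels = corpus_io.read_qrels(directory / "qrels.tsv")
    return Corpus(
        references=tuple(refs),
        pairs=tuple(corpus_io.read_pairs(directory / "pairs.tsv")),
        candidates=corpus_io.read_candidates(directory / "candidates.tsv"),
        qrels={p: frozenset(t) for p, t in qrels.items()},
        gene_thesaurus=corpus_io.read_thesaurus(
            directory / "gene_thesaurus.tsv", "gene"
        ),
        disease_thesaurus=corpus_io.read_thesaurus(
            directory / "disease_thesaurus.tsv", "disease"
        ),
        config=None,
    )
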