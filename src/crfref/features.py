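"""The thirteen conclusiveness / richness / focus factors.

Given a reference *r* and a gene-disease pair <g, d>, the ranker scores
*r* by how conclusively, richly and focusedly it treats the pair:

* **conclusiveness** (factors 1-7): a short reference in which g and d
  occur repeatedly, in the title, and near the end is likely to *conclude*
  something about the pair.  Length is |r|/AvgLen capped at 1; the term
  frequencies are capped at three occurrences (min(TF/3, 1)); the title
  factors are indicators; the ending factors are the 1-based position of
  the last mention divided by |r|.
* **richness** (factors 8-9): the number of *distinct* other genes and
  other diseases mentioned, squashed into [0, 1) as c/(c+1) — extra
  entities suggest the author supplied supporting context.
* **focus** (factors 10-13): the title/ending counterparts of 4-7 applied
  to the other genes and diseases; conclusive treatment of a different
  entity dilutes the conclusion about <g, d>.  Ending factors take the
  maximum over distractor entities.

All factors lie in [0, 1] and factors for absent entities are 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import QueryPair, Reference, Thesaurus
from .entity_match import MentionIndex, find_mentions

__all__ = [
    "FACTOR_NAMES",
    "VARIANTS",
    "CorpusStats",
    "compute_corpus_stats",
    "conclusiveness_factors",
    "richness_factors",
    "focus_factors",
    "assemble",
    "crfref_features",
    "write_feature_matrix",
]

FACTOR_NAMES = (
    "length",
    "gene_tf",
    "disease_tf",
    "gene_at_title",
    "disease_at_title",
    "gene_at_ending",
    "disease_at_ending",
    "not_gene_num",
    "not_disease_num",
    "not_gene_at_title",
    "not_disease_at_title",
    "not_gene_at_ending",
    "not_disease_at_ending",
)

#: ablation variants -> number of leading factors used
VARIANTS = {"conclusiveness": 7, "conclusiveness_richness": 9, "full": 13}

# TF saturation: three mentions of an entity already signal salience.
_TF_CAP = 3.0


@dataclass(frozen=True)
class CorpusStats:
    """Training-corpus statistics: size, mean length, document frequencies.

    ``df[e]`` is the number of training references containing at least one
    mention of entity ``e`` (the *n* of the BM25 idf).  Computed from the
    training folds only, never from held-out data.
    """

    n_refs: int
    avg_len: float
    df: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_refs < 1:
            raise ValueError("corpus statistics need at least one reference")
        if not self.avg_len > 0:
            raise ValueError("average reference length must be positive")

    def df_of(self, entity_id: str) -> int:
        return self.df.get(entity_id, 0)


def compute_corpus_stats(
    refs: Sequence[Reference],
    gene_thesaurus: Thesaurus | None = None,
    disease_thesaurus: Thesaurus | None = None,
    mentions: Mapping[str, tuple[MentionIndex, MentionIndex]] | None = None,
) -> CorpusStats:
    """Compute N, AvgLen and per-entity document frequencies over ``refs``.

    ``mentions`` may supply precomputed (gene, disease) mention indexes per
    ref_id; otherwise both thesauri are scanned here.
    """
    if not refs:
        raise ValueError("empty training corpus")
    df: dict[str, int] = {}
    total_len = 0
    for ref in refs:
        total_len += len(ref)
        if mentions is not None:
            gmi, dmi = mentions[ref.ref_id]
        else:
            if gene_thesaurus is None or disease_thesaurus is None:
                raise ValueError("need thesauri or precomputed mentions")
            gmi = find_mentions(ref, gene_thesaurus)
            dmi = find_mentions(ref, disease_thesaurus)
        for eid in gmi.entities() | dmi.entities():
            df[eid] = df.get(eid, 0) + 1
    return CorpusStats(len(refs), total_len / len(refs), df)


def conclusiveness_factors(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
    stats: CorpusStats,
) -> np.ndarray:
    """Factors 1-7: length, capped TFs, title flags, ending positions."""
    n = len(ref)
    if n == 0:
        raise ValueError(f"reference {ref.ref_id!r} has no tokens")
    out = np.zeros(7)
    out[0] = min(n / stats.avg_len, 1.0)
    out[1] = min(gene_mentions.tf(pair.gene_id) / _TF_CAP, 1.0)
    out[2] = min(disease_mentions.tf(pair.disease_id) / _TF_CAP, 1.0)
    out[3] = 1.0 if gene_mentions.in_title(pair.gene_id) else 0.0
    out[4] = 1.0 if disease_mentions.in_title(pair.disease_id) else 0.0
    out[5] = gene_mentions.last_end(pair.gene_id) / n
    out[6] = disease_mentions.last_end(pair.disease_id) / n
    return out


def _distractors(mentions: MentionIndex, exclude: str) -> set[str]:
    return mentions.entities() - {exclude}


def richness_factors(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
) -> np.ndarray:
    """Factors 8-9: distinct other-gene / other-disease counts, squashed."""
    c_g = len(_distractors(gene_mentions, pair.gene_id))
    c_d = len(_distractors(disease_mentions, pair.disease_id))
    return np.array([c_g / (c_g + 1.0), c_d / (c_d + 1.0)])


def focus_factors(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
) -> np.ndarray:
    """Factors 10-13: title flags and max ending scores over distractors."""
    n = len(ref)
    if n == 0:
        raise ValueError(f"reference {ref.ref_id!r} has no tokens")
    out = np.zeros(4)
    for j, (mi, query_eid) in enumerate(
        [(gene_mentions, pair.gene_id), (disease_mentions, pair.disease_id)]
    ):
        others = _distractors(mi, query_eid)
        out[j] = 1.0 if any(mi.in_title(e) for e in others) else 0.0
        out[2 + j] = max((mi.last_end(e) / n for e in others), default=0.0)
    return out


def assemble(
    ref: Reference,
    pair: QueryPair,
    gene_mentions: MentionIndex,
    disease_mentions: MentionIndex,
    stats: CorpusStats,
    variant: str = "full",
) -> np.ndarray:
    """Return the factor vector for an ablation variant (7, 9 or 13 long)."""
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
        )
    full = np.concatenate(
        [
            conclusiveness_factors(ref, pair, gene_mentions, disease_mentions, stats),
            richness_factors(ref, pair, gene_mentions, disease_mentions),
            focus_factors(ref, pair, gene_mentions, disease_mentions),
        ]
    )
    return full[: VARIANTS[variant]]


def crfref_features(
    ref: Reference,
    pair: QueryPair,
    gene_thesaurus: Thesaurus,
    disease_thesaurus: Thesaurus,
    stats: CorpusStats,
    variant: str = "full",
) -> np.ndarray:
    """Convenience wrapper that scans both thesauri and assembles factors."""
    gmi = find_mentions(ref, gene_thesaurus)
    dmi = find_mentions(ref, disease_thesaurus)
    return assemble(ref, pair, gmi, dmi, stats, variant)


def write_feature_matrix(
    path: str | Path,
    rows: Iterable[tuple[str, str, int, np.ndarray]],
) -> None:
    """Export (pair_id, ref_id, label, factors) rows as a TSV for audit."""
    with open(path, "w", encoding="utf-8") as fh:
        header = None
        for pair_id, ref_id, label, vec in rows:
            if header is None:
                names = FACTOR_NAMES[: len(vec)]
                header = "pair_id\tref_id\tlabel\t" + "\t".join(names)
                fh.write(header + "\n")
            vals = "\t".join(format(v, ".10g") for v in vec)
            fh.write(f"{pair_id}\t{ref_id}\t{label}\t{vals}\n")
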