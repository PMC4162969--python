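"""Dictionary matching of thesaurus aliases in references.

Matching is exact on normalized tokens ("strict term matching"): a
left-to-right greedy scan over the reference body in which, at each
position, the longest alias matching there wins and the scan resumes
after it.  When aliases owned by different entities tie for the longest
span, every owning entity is credited with a match.  Matches never
straddle the title/abstract boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_io import QueryPair, Reference, Thesaurus

__all__ = ["Mention", "MentionIndex", "find_mentions", "filter_candidates"]


@dataclass(frozen=True)
class Mention:
    """One alias match: ``start`` is a 0-based token index into the body."""

    entity_id: str
    start: int
    length: int
    in_title: bool

    @property
    def end(self) -> int:
        """1-based index of the final token of the match."""
        return self.start + self.length


class MentionIndex:
    """Per-reference positions of each entity's alias matches."""

    def __init__(self, ref_len: int, mentions: Iterable[Mention] = ()):
        self.ref_len = ref_len
        self._by_entity: dict[str, list[Mention]] = {}
        for m in mentions:
            if m.start + m.length > ref_len:
                raise ValueError("mention extends past reference body")
            self._by_entity.setdefault(m.entity_id, []).append(m)
        for ms in self._by_entity.values():
            ms.sort(key=lambda m: (m.start, m.length))

    def matches(self, entity_id: str) -> list[Mention]:
        return self._by_entity.get(entity_id, [])

    def tf(self, entity_id: str, title: bool = True, abstract: bool = True) -> int:
        """Number of matches; restrict to title or abstract via the flags."""
        return sum(
            1
            for m in self.matches(entity_id)
            if (title and m.in_title) or (abstract and not m.in_title)
        )

    def last_end(self, entity_id: str) -> int:
        """1-based final-token index of the entity's last match; 0 if absent."""
        ms = self.matches(entity_id)
        return max(m.end for m in ms) if ms else 0

    def in_title(self, entity_id: str) -> bool:
        return any(m.in_title for m in self.matches(entity_id))

    def entities(self) -> set[str]:
        return set(self._by_entity)


def _alias_lookup(
    thesaurus: Thesaurus, entity_ids: Iterable[str] | None
) -> dict[str, list[tuple[tuple[str, ...], list[str]]]]:
    """First-token -> [(alias tokens, owning entity ids)] for the scan."""
    wanted = set(entity_ids) if entity_ids is not None else None
    lookup: dict[str, dict[tuple[str, ...], list[str]]] = {}
    for eid, aliases in thesaurus.entries.items():
        if wanted is not None and eid not in wanted:
            continue
        for alias in aliases:
            owners = lookup.setdefault(alias[0], {}).setdefault(alias, [])
            if eid not in owners:
                owners.append(eid)
    return {
        head: sorted(d.items(), key=lambda kv: -len(kv[0]))
        for head, d in lookup.items()
    }


def _scan(
    tokens: Sequence[str],
    offset: int,
    in_title: bool,
    lookup: Mapping[str, list[tuple[tuple[str, ...], list[str]]]],
    out: list[Mention],
) -> None:
    i = 0
    n = len(tokens)
    while i < n:
        best_len = 0
        owners: list[str] = []
        for alias, eids in lookup.get(tokens[i], ()):
            length = len(alias)
            if length < best_len:
                break  # lookup sorted longest-first
            if i + length <= n and tuple(tokens[i : i + length]) == alias:
                if length > best_len:
                    best_len = length
                    owners = list(eids)
                else:
                    owners.extend(e for e in eids if e not in owners)
        if best_len:
            for eid in owners:
                out.append(Mention(eid, offset + i, best_len, in_title))
            i += best_len
        else:
            i += 1


def find_mentions(
    ref: Reference,
    thesaurus: Thesaurus,
    entity_ids: Iterable[str] | None = None,
) -> MentionIndex:
    """Locate all alias matches of the requested entities in ``ref``.

    ``entity_ids=None`` scans the whole thesaurus.  The title and the
    abstract are scanned separately so a match never crosses the boundary;
    positions are reported over the concatenated body.
    """
    lookup = _alias_lookup(thesaurus, entity_ids)
    mentions: list[Mention] = []
    _scan(ref.title_tokens, 0, True, lookup, mentions)
    _scan(ref.abstract_tokens, len(ref.title_tokens), False, lookup, mentions)
    return MentionIndex(len(ref), mentions)


def filter_candidates(
    refs: Iterable[Reference],
    pair: QueryPair,
    gene_thesaurus: Thesaurus,
    disease_thesaurus: Thesaurus,
) -> list[Reference]:
    """Keep the references that mention both the query gene and disease.

    Aliases count as the entity; input order is preserved.
    """
    kept = []
    for ref in refs:
        gmi = find_mentions(ref, gene_thesaurus)
        dmi = find_mentions(ref, disease_thesaurus)
        if gmi.tf(pair.gene_id) >= 1 and dmi.tf(pair.disease_id) >= 1:
            kept.append(ref)
    return kept
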