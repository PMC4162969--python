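"""Readers, writers and text normalization for reference corpora.

The on-disk dialects are deliberately plain text: a JSON-lines file for
title/abstract records (one object per line with keys ``id``, ``title``,
``abstract`` and optionally ``sentences``), MEDLINE flat files with
``PMID``/``TI``/``AB`` tags, and tab-separated files for thesauri, query
pairs, per-pair candidate lists and relevance judgments (qrels).

All text passes through :func:`normalize_text` before any matching or
scoring: every non-alphanumeric character becomes a space and tokens are
lowercased unless their alphabetic characters are all uppercase (so gene
symbols such as ``BRCA1`` keep their casing while mixed-case words like
``HbS`` fold to lowercase).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "normalize_text",
    "split_sentences",
    "Reference",
    "Thesaurus",
    "QueryPair",
    "make_reference",
    "read_references",
    "write_references",
    "read_thesaurus",
    "write_thesaurus",
    "read_pairs",
    "write_pairs",
    "read_qrels",
    "write_qrels",
    "read_candidates",
    "write_candidates",
]

_NON_ALNUM = re.compile(r"[^0-9A-Za-z]+")
_SENT_SPLIT = re.compile(r"\.\s+")


def normalize_text(raw: str) -> list[str]:
    """Tokenize ``raw`` under the corpus normalization rule.

    Every non-alphanumeric character is replaced by a space and the result
    split on whitespace.  Each token is lowercased unless it contains at
    least two alphabetic characters and all of them are uppercase, in which
    case the token is preserved verbatim (all-caps symbols carry meaning;
    a lone capital letter does not).

    The function is idempotent: re-normalizing the joined output is a
    no-op.
    """
    out: list[str] = []
    for tok in _NON_ALNUM.sub(" ", raw).split():
        letters = [c for c in tok if c.isalpha()]
        if len(letters) >= 2 and all(c.isupper() for c in letters):
            out.append(tok)
        else:
            out.append(tok.lower())
    return out


def split_sentences(raw_abstract: str) -> list[str]:
    """Split a raw abstract into sentence strings on period-plus-whitespace."""
    return [s for s in _SENT_SPLIT.split(raw_abstract) if s.strip()]


@dataclass(frozen=True)
class Reference:
    """One candidate abstract after normalization.

    ``sentence_bounds`` are half-open ``(start, end)`` token spans over
    ``abstract_tokens``; they partition the abstract in order.  The *body*
    of the reference is the title followed by the abstract, and token
    positions used elsewhere (mention matching, ending scores) are 0-based
    indices into that concatenation.
    """

    ref_id: str
    title_tokens: tuple[str, ...]
    abstract_tokens: tuple[str, ...]
    sentence_bounds: tuple[tuple[int, int], ...]

    @property
    def body(self) -> tuple[str, ...]:
        return self.title_tokens + self.abstract_tokens

    def __len__(self) -> int:
        return len(self.title_tokens) + len(self.abstract_tokens)


def make_reference(
    ref_id: str,
    title: str,
    abstract: str = "",
    sentences: Sequence[str] | None = None,
) -> Reference:
    """Build a :class:`Reference` from raw strings.

    Sentence boundaries are taken from ``sentences`` when supplied
    (fixtures can then be exact); otherwise the raw abstract is split on
    period-plus-whitespace before tokenization.
    """
    if not ref_id:
        raise ValueError("reference requires a non-empty id")
    title_tokens = tuple(normalize_text(title))
    if sentences is None:
        sentences = split_sentences(abstract)
    bounds: list[tuple[int, int]] = []
    abstract_tokens: list[str] = []
    for sent in sentences:
        toks = normalize_text(sent)
        if not toks:
            continue
        start = len(abstract_tokens)
        abstract_tokens.extend(toks)
        bounds.append((start, len(abstract_tokens)))
    if not title_tokens and not abstract_tokens:
        raise ValueError(f"reference {ref_id!r} has empty title and abstract")
    return Reference(ref_id, title_tokens, tuple(abstract_tokens), tuple(bounds))


@dataclass(frozen=True)
class Thesaurus:
    """Entity -> alias-set dictionary for genes or diseases.

    Aliases are stored as normalized token tuples.  An alias may belong to
    more than one entity (ambiguous symbols are real); each owning entry
    records it.
    """

    kind: str
    entries: Mapping[str, tuple[tuple[str, ...], ...]]

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "disease"):
            raise ValueError(f"unknown thesaurus kind {self.kind!r}")
        for eid, aliases in self.entries.items():
            if not aliases:
                raise ValueError(f"entity {eid!r} has no aliases")
            for alias in aliases:
                if not alias:
                    raise ValueError(f"entity {eid!r} has an empty alias")

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class QueryPair:
    """A gene-disease query; both ids must resolve in their thesauri."""

    pair_id: str
    gene_id: str
    disease_id: str


# ---------------------------------------------------------------------------
# references

def read_references(path: str | Path, format: str = "jsonl") -> list[Reference]:
    path = Path(path)
    if format == "jsonl":
        return _read_references_jsonl(path)
    if format == "medline":
        return _read_references_medline(path)
    raise ValueError(f"unknown reference format {format!r}")


def _read_references_jsonl(path: Path) -> list[Reference]:
    refs: list[Reference] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON record") from exc
            if not isinstance(rec, dict) or not rec.get("id"):
                raise ValueError(f"{path}:{lineno}: record missing 'id'")
            refs.append(
                make_reference(
                    str(rec["id"]),
                    rec.get("title", ""),
                    rec.get("abstract", ""),
                    sentences=rec.get("sentences"),
                )
            )
    return refs


def _read_references_medline(path: Path) -> list[Reference]:
    from Bio import Medline

    refs: list[Reference] = []
    with open(path, encoding="utf-8") as fh:
        for recno, rec in enumerate(Medline.parse(fh), start=1):
            pmid = rec.get("PMID")
            if not pmid:
                raise ValueError(f"{path}: record {recno} missing PMID")
            refs.append(make_reference(str(pmid), rec.get("TI", ""), rec.get("AB", "")))
    return refs


def write_references(path: str | Path, refs: Iterable[Reference]) -> None:
    """Write references as JSON lines, preserving exact sentence splits."""
    with open(path, "w", encoding="utf-8") as fh:
        for ref in refs:
            rec = {
                "id": ref.ref_id,
                "title": " ".join(ref.title_tokens),
                "abstract": " ".join(ref.abstract_tokens),
                "sentences": [
                    " ".join(ref.abstract_tokens[a:b]) for a, b in ref.sentence_bounds
                ],
            }
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# thesauri

def read_thesaurus(path: str | Path, kind: str) -> Thesaurus:
    """Read a TSV thesaurus: ``entity_id TAB alias1|alias2|...`` per row."""
    path = Path(path)
    entries: dict[str, tuple[tuple[str, ...], ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: row has no alias field")
            eid = parts[0].strip()
            aliases: list[tuple[str, ...]] = []
            for raw_alias in parts[1].split("|"):
                toks = tuple(normalize_text(raw_alias))
                if not toks:
                    raise ValueError(f"{path}:{lineno}: alias normalizes to nothing")
                if toks not in aliases:
                    aliases.append(toks)
            entries[eid] = tuple(aliases)
    if not entries:
        raise ValueError(f"{path}: empty thesaurus")
    return Thesaurus(kind, entries)


def write_thesaurus(path: str | Path, thesaurus: Thesaurus) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for eid, aliases in thesaurus.entries.items():
            fh.write(eid + "\t" + "|".join(" ".join(a) for a in aliases) + "\n")


# ---------------------------------------------------------------------------
# pairs, candidates, qrels

def read_pairs(path: str | Path) -> list[QueryPair]:
    pairs: list[QueryPair] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected pair_id, gene_id, disease_id")
            pairs.append(QueryPair(*[p.strip() for p in parts]))
    return pairs


def write_pairs(path: str | Path, pairs: Iterable[QueryPair]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.gene_id}\t{p.disease_id}\n")


def read_qrels(path: str | Path) -> dict[str, set[str]]:
    """Read qrels TSV (``pair_id TAB ref_id TAB label``) into pair -> target set.

    Rows with label 0 register the pair without adding a target, so pairs
    with no target references at all are representable.
    """
    qrels: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: expected pair_id, ref_id, label in {{0,1}}")
            qrels.setdefault(parts[0], set())
            if parts[2] == "1":
                qrels[parts[0]].add(parts[1])
    return qrels


def write_qrels(
    path: str | Path,
    qrels: Mapping[str, set[str]],
    candidates: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """Write qrels; when ``candidates`` is given, emit a labelled row per candidate."""
    with open(path, "w", encoding="utf-8") as fh:
        for pair_id in sorted(qrels):
            targets = qrels[pair_id]
            ref_ids = candidates[pair_id] if candidates is not None else sorted(targets)
            for ref_id in ref_ids:
                label = 1 if ref_id in targets else 0
                fh.write(f"{pair_id}\t{ref_id}\t{label}\n")


def read_candidates(path: str | Path) -> dict[str, list[str]]:
    """Read per-pair candidate lists (``pair_id TAB ref_id``), order preserved."""
    cands: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected pair_id, ref_id")
            cands.setdefault(parts[0], []).append(parts[1])
    return cands


def write_candidates(path: str | Path, candidates: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pair_id in sorted(candidates):
            for ref_id in candidates[pair_id]:
                fh.write(f"{pair_id}\t{ref_id}\n")
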