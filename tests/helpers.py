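"""Independent brute-force oracles used across the test suite.

These deliberately re-derive results from first principles (substring
enumeration, direct counting, literal prose definitions) rather than
calling the library's own scan/score paths, so agreement is evidence and
not tautology.
"""

from __future__ import annotations

import math

import numpy as np

from crfref.corpus_io import QueryPair, Reference, Thesaurus


def brute_force_matches(ref: Reference, thesaurus: Thesaurus):
    """Enumerate every (position, alias) match, then resolve greedily.

    Returns a dict entity_id -> list of (start, length, in_title), the
    same resolution rule as the scanner: longest alias at the current
    position wins (all owners credited), scan resumes after it.
    """
    regions = [
        (list(ref.title_tokens), 0, True),
        (list(ref.abstract_tokens), len(ref.title_tokens), False),
    ]
    out: dict[str, list[tuple[int, int, bool]]] = {}
    for tokens, offset, in_title in regions:
        # all candidate matches at every position
        at: dict[int, list[tuple[int, str]]] = {}
        for eid, aliases in thesaurus.entries.items():
            for alias in aliases:
                L = len(alias)
                for i in range(len(tokens) - L + 1):
                    if tuple(tokens[i : i + L]) == alias:
                        at.setdefault(i, []).append((L, eid))
        i = 0
        while i < len(tokens):
            if i in at:
                best = max(L for L, _ in at[i])
                for L, eid in at[i]:
                    if L == best:
                        out.setdefault(eid, []).append((offset + i, L, in_title))
                i += best
            else:
                i += 1
    return out


def slow_factors(
    ref: Reference,
    pair: QueryPair,
    gene_thesaurus: Thesaurus,
    disease_thesaurus: Thesaurus,
    avg_len: float,
) -> np.ndarray:
    """Literal re-implementation of the 13 factor definitions."""
    n = len(ref)
    gm = brute_force_matches(ref, gene_thesaurus)
    dm = brute_force_matches(ref, disease_thesaurus)

    def tf(m, eid):
        return len(m.get(eid, []))

    def at_title(m, eid):
        return 1.0 if any(t for _, _, t in m.get(eid, [])) else 0.0

    def last_end(m, eid):
        ms = m.get(eid, [])
        return max(s + L for s, L, _ in ms) if ms else 0

    f = np.zeros(13)
    f[0] = min(n / avg_len, 1.0)
    f[1] = min(tf(gm, pair.gene_id) / 3.0, 1.0)
    f[2] = min(tf(dm, pair.disease_id) / 3.0, 1.0)
    f[3] = at_title(gm, pair.gene_id)
    f[4] = at_title(dm, pair.disease_id)
    f[5] = last_end(gm, pair.gene_id) / n
    f[6] = last_end(dm, pair.disease_id) / n
    other_g = [e for e in gm if e != pair.gene_id]
    other_d = [e for e in dm if e != pair.disease_id]
    f[7] = len(other_g) / (len(other_g) + 1.0)
    f[8] = len(other_d) / (len(other_d) + 1.0)
    f[9] = 1.0 if any(at_title(gm, e) for e in other_g) else 0.0
    f[10] = 1.0 if any(at_title(dm, e) for e in other_d) else 0.0
    f[11] = max((last_end(gm, e) / n for e in other_g), default=0.0)
    f[12] = max((last_end(dm, e) / n for e in other_d), default=0.0)
    return f


def brute_average_precision(ranking, targets) -> float:
    """AP as mean of precision at each target's rank."""
    if not targets:
        return 0.0
    precisions = []
    for j, ref_id in enumerate(ranking, start=1):
        if ref_id in targets:
            hits_so_far = sum(1 for r in ranking[:j] if r in targets)
            precisions.append(hits_so_far / j)
    return sum(precisions) / len(targets)


def brute_bm25(tf, n_refs, df, doc_len, avg_len, k1=2.0, b=0.75) -> float:
    """Single-term Okapi contribution, written independently."""
    if tf <= 0:
        return 0.0
    idf = math.log((n_refs - df + 0.5) / (df + 0.5))
    idf = idf if idf > 0 else 0.0
    return idf * (tf * (k1 + 1)) / (tf + k1 * (1 - b + b * doc_len / avg_len))


def brute_vsm(tf, n_refs, df, doc_len) -> float:
    if tf <= 0:
        return 0.0
    idf = 1.0 + math.log(n_refs / (df + 1.0))
    return math.sqrt(tf) * idf * idf / math.sqrt(doc_len)


def brute_proximity_boost(g_starts, d_starts, sigma) -> float:
    return sum(
        math.exp(-((i - j) ** 2) / (2 * sigma**2))
        for i in g_starts
        for j in d_starts
    )
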