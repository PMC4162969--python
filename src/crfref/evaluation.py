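"""Retrieval evaluation: AP/MAP, P@X, fraction of pairs with hits,
query-level k-fold splitting, and the dual significance rule.

Average precision follows the standard convention: with targets indexed
1..k in rank order, AP = (1/k) * sum_j j / rank_of_jth_target.  Queries
with no targets score AP = 0 and P@X = 0 rather than being dropped —
rankers must work on uncorrelated pairs too, and including them keeps the
mean comparable across systems.

Two systems differ *significantly* only when both the paired t-test and
the Wilcoxon signed-rank test (zero differences dropped) reject at the
chosen level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankedRun",
    "FoldPlan",
    "SignificanceVerdict",
    "average_precision",
    "mean_average_precision",
    "precision_at_x",
    "fraction_pairs_positive",
    "make_folds",
    "compare_significance",
    "write_metrics_report",
]


@dataclass(frozen=True)
class RankedRun:
    """Ordered candidates for one query plus its target set."""

    pair_id: str
    ranking: tuple[str, ...]
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError(f"run {self.pair_id!r}: duplicate ref_ids in ranking")
        if self.targets and not self.targets <= set(self.ranking):
            raise ValueError(
                f"run {self.pair_id!r}: targets outside the candidate set"
            )


def average_precision(run: RankedRun) -> float:
    """AP of one run; 0 when the query has no targets."""
    if not run.ranking:
        raise ValueError(f"run {run.pair_id!r}: empty candidate list")
    if not run.targets:
        return 0.0
    hits = 0
    total = 0.0
    for rank, ref_id in enumerate(run.ranking, start=1):
        if ref_id in run.targets:
            hits += 1
            total += hits / rank
    return total / len(run.targets)


def mean_average_precision(runs: Sequence[RankedRun]) -> float:
    """Mean AP over all queries, zero-target queries included."""
    if not runs:
        raise ValueError("no runs to average")
    return float(np.mean([average_precision(r) for r in runs]))


def precision_at_x(run: RankedRun, x: int) -> float:
    """Targets among the top-x over x (denominator stays x when short)."""
    if x < 1:
        raise ValueError("X must be at least 1")
    return sum(1 for ref_id in run.ranking[:x] if ref_id in run.targets) / x


def fraction_pairs_positive(runs: Sequence[RankedRun], x: int) -> float:
    """Fraction of queries with at least one target in the top-x."""
    if not runs:
        raise ValueError("no runs")
    return sum(1 for r in runs if precision_at_x(r, x) > 0) / len(runs)


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint query folds for cross-validation."""

    folds: tuple[frozenset[str], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_test(self, i: int) -> tuple[set[str], set[str]]:
        test = set(self.folds[i])
        train = set().union(*(f for j, f in enumerate(self.folds) if j != i))
        return train, test


def make_folds(pair_ids: Iterable[str], k: int = 4, seed: int = 0) -> FoldPlan:
    """Seeded shuffle then round-robin split into k near-equal folds."""
    ids = sorted(set(pair_ids))
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} queries into {k} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    return FoldPlan(
        folds=tuple(frozenset(order[i::k]) for i in range(k)),
        seed=seed,
    )


@dataclass(frozen=True)
class SignificanceVerdict:
    p_ttest: float
    p_wilcoxon: float
    significant: bool
    degenerate: bool = False


def compare_significance(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    alpha: float = 0.05,
) -> SignificanceVerdict:
    """Dual paired test on per-query metric values (AP or P@X).

    Significant only if both the paired t-test and the Wilcoxon
    signed-rank test (zero-difference queries dropped) give p <= alpha.
    Identical vectors yield a degenerate not-significant verdict.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors differ in length")
    if a.size < 5:
        raise ValueError("need at least 5 paired queries")
    d = b - a
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return SignificanceVerdict(1.0, 1.0, False, degenerate=True)
    if np.std(d, ddof=1) <= 1e-12 * max(1.0, float(np.max(np.abs(d)))):
        # constant nonzero shift: t statistic is unbounded
        p_t = 0.0
    else:
        p_t = float(sps.ttest_rel(b, a).pvalue)
    p_w = float(sps.wilcoxon(nonzero).pvalue)
    return SignificanceVerdict(p_t, p_w, bool(p_t <= alpha and p_w <= alpha))


def write_metrics_report(
    path,
    per_pair: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> None:
    """Per-pair metric TSV: ranker, pair_id, then one column per metric."""
    metric_names: list[str] = []
    for pair_metrics in per_pair.values():
        for metrics in pair_metrics.values():
            metric_names = sorted(metrics)
            break
        break
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ranker\tpair_id\t" + "\t".join(metric_names) + "\n")
        for ranker in sorted(per_pair):
            for pair_id in sorted(per_pair[ranker]):
                metrics = per_pair[ranker][pair_id]
                vals = "\t".join(format(metrics[m], ".6f") for m in metric_names)
                fh.write(f"{ranker}\t{pair_id}\t{vals}\n")
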