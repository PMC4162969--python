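"""End-to-end cross-validated ranking experiments.

Runs the full protocol on a :class:`~crfref.synthetic.Corpus`: split the
query pairs into k folds, compute corpus statistics (N, AvgLen, document
frequencies) and feature scalers from the training folds only, train the
pairwise ranker where the ranker has trainable features, rank the
held-out pairs, pool per-pair metrics over folds and apply the dual
significance rule against a reference ranker.

Ranker names
------------
Score-only rankers (ranked directly by their score):
``bm25``, ``vsm``, ``proximity_bm25``.
Feature rankers (integrated by the pairwise SVM): ``posfreq``,
``crfref_conclusiveness``, ``crfref_conclusiveness_richness``,
``crfref_full``.  Integrative rankers concatenate components with ``+``,
e.g. ``bm25+posfreq`` or ``crfref_full+bm25+posfreq``; any combination is
trained, with scalar scores entering as one feature each.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import baselines, features, ranker
from .corpus_io import QueryPair, Reference
from .entity_match import MentionIndex, find_mentions
from .evaluation import (
    FoldPlan,
    RankedRun,
    SignificanceVerdict,
    average_precision,
    compare_significance,
    fraction_pairs_positive,
    make_folds,
    mean_average_precision,
    precision_at_x,
    write_metrics_report,
)
from .features import CorpusStats, VARIANTS, compute_corpus_stats
from .synthetic import Corpus

__all__ = [
    "SCORE_RANKERS",
    "FEATURE_RANKERS",
    "ExperimentResult",
    "valid_ranker",
    "run_experiment",
]

SCORE_RANKERS = ("bm25", "vsm", "proximity_bm25")
FEATURE_RANKERS = (
    "posfreq",
    "crfref_conclusiveness",
    "crfref_conclusiveness_richness",
    "crfref_full",
)


def valid_ranker(name: str) -> bool:
    parts = name.split("+")
    return all(p in SCORE_RANKERS or p in FEATURE_RANKERS for p in parts)


def _component_vector(
    part: str,
    ref: Reference,
    pair: QueryPair,
    gmi: MentionIndex,
    dmi: MentionIndex,
    stats: CorpusStats,
) -> np.ndarray:
    if part == "bm25":
        return np.array([baselines.bm25_score(ref, pair, gmi, dmi, stats)])
    if part == "vsm":
        return np.array([baselines.vsm_score(ref, pair, gmi, dmi, stats)])
    if part == "proximity_bm25":
        return np.array([baselines.proximity_bm25_score(ref, pair, gmi, dmi, stats)])
    if part == "posfreq":
        return baselines.posfreq_features(ref, pair, gmi, dmi)
    if part.startswith("crfref_"):
        variant = part[len("crfref_"):]
        return features.assemble(ref, pair, gmi, dmi, stats, variant)
    raise ValueError(f"unknown ranker component {part!r}")


def _feature_vector(
    name: str,
    ref: Reference,
    pair: QueryPair,
    gmi: MentionIndex,
    dmi: MentionIndex,
    stats: CorpusStats,
) -> np.ndarray:
    return np.concatenate(
        [_component_vector(p, ref, pair, gmi, dmi, stats) for p in name.split("+")]
    )


@dataclass
class ExperimentResult:
    """Pooled cross-validation outcome for a roster of rankers."""

    rankers: tuple[str, ...]
    folds: FoldPlan
    px: tuple[int, ...]
    runs: dict[str, dict[str, RankedRun]]            # ranker -> pair -> run
    per_pair: dict[str, dict[str, dict[str, float]]]  # ranker -> pair -> metric
    summary: dict[str, dict[str, float]]              # ranker -> metric
    significance: dict[str, dict[str, SignificanceVerdict]]
    reference_ranker: str
    log: list[str] = field(default_factory=list)

    def ap_vector(self, name: str) -> np.ndarray:
        pair_ids = sorted(self.per_pair[name])
        return np.array([self.per_pair[name][p]["ap"] for p in pair_ids])


def run_experiment(
    corpus: Corpus,
    rankers: Sequence[str],
    k: int = 4,
    seed: int = 0,
    alpha: float = 0.05,
    px: Sequence[int] = (1, 2, 3),
    c_reg: float = 1.0,
    reference_ranker: str | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Cross-validate every ranker on ``corpus`` and compare them.

    Statistics and scalers are computed per training fold, so no held-out
    information leaks into training.  All randomness (fold assignment,
    SVM solver) is derived from ``seed``.
    """
    if not rankers:
        raise ValueError("no rankers requested")
    for name in rankers:
        if not valid_ranker(name):
            raise ValueError(
                f"unknown ranker {name!r}; components must come from "
                f"{SCORE_RANKERS + FEATURE_RANKERS}"
            )
    # duplicate roster entries get distinct display names (name#2, ...)
    display: list[str] = []
    base_of: dict[str, str] = {}
    seen_counts: dict[str, int] = {}
    for name in rankers:
        seen_counts[name] = seen_counts.get(name, 0) + 1
        disp = name if seen_counts[name] == 1 else f"{name}#{seen_counts[name]}"
        display.append(disp)
        base_of[disp] = name
    rankers = display
    reference_ranker = reference_ranker or rankers[0]
    if reference_ranker not in rankers:
        raise ValueError(f"reference ranker {reference_ranker!r} not in roster")

    t0 = time.perf_counter()
    log = [f"seed={seed} k={k} alpha={alpha} px={tuple(px)} c_reg={c_reg}"]
    ref_map = corpus.reference_map()
    pair_map = {p.pair_id: p for p in corpus.pairs}

    # mention scans are thesaurus-wide and fold-independent: do them once
    mentions = {
        r.ref_id: (
            find_mentions(r, corpus.gene_thesaurus),
            find_mentions(r, corpus.disease_thesaurus),
        )
        for r in corpus.references
    }

    folds = make_folds(pair_map, k=k, seed=seed)
    log.append("fold sizes: " + ",".join(str(len(f)) for f in folds.folds))

    runs: dict[str, dict[str, RankedRun]] = {name: {} for name in rankers}
    for i in range(folds.k):
        train_pairs, test_pairs = folds.train_test(i)
        train_ref_ids: list[str] = []
        seen: set[str] = set()
        for pid in sorted(train_pairs):
            for rid in corpus.candidates[pid]:
                if rid not in seen:
                    seen.add(rid)
                    train_ref_ids.append(rid)
        stats = compute_corpus_stats(
            [ref_map[rid] for rid in train_ref_ids], mentions=mentions
        )
        log.append(
            f"fold {i}: train_pairs={len(train_pairs)} test_pairs={len(test_pairs)} "
            f"train_refs={stats.n_refs} avg_len={stats.avg_len:.2f}"
        )

        for name in rankers:
            base = base_of[name]
            trained = "+" in base or base in FEATURE_RANKERS
            model = None
            if trained:
                ts = {}
                for pid in sorted(train_pairs):
                    pair = pair_map[pid]
                    rows, labels = [], []
                    for rid in corpus.candidates[pid]:
                        ref = ref_map[rid]
                        gmi, dmi = mentions[rid]
                        rows.append(_feature_vector(base, ref, pair, gmi, dmi, stats))
                        labels.append(1 if rid in corpus.qrels.get(pid, frozenset()) else 0)
                    ts[pid] = (np.vstack(rows), np.array(labels))
                model = ranker.train_pairwise(ts, c_reg=c_reg, seed=seed)
            for pid in sorted(test_pairs):
                pair = pair_map[pid]
                items = []
                for rid in corpus.candidates[pid]:
                    ref = ref_map[rid]
                    gmi, dmi = mentions[rid]
                    items.append(
                        (rid, _feature_vector(base, ref, pair, gmi, dmi, stats))
                    )
                if trained:
                    ordered = ranker.rank_candidates(model, pid, items)
                else:
                    ordered = sorted(
                        ((rid, float(x[0])) for rid, x in items),
                        key=lambda t: (-t[1], t[0]),
                    )
                runs[name][pid] = RankedRun(
                    pid,
                    tuple(rid for rid, _ in ordered),
                    frozenset(corpus.qrels.get(pid, frozenset())),
                )

    px = tuple(px)
    per_pair: dict[str, dict[str, dict[str, float]]] = {}
    summary: dict[str, dict[str, float]] = {}
    for name in rankers:
        pp: dict[str, dict[str, float]] = {}
        for pid, run in runs[name].items():
            metrics = {"ap": average_precision(run)}
            for x in px:
                metrics[f"p@{x}"] = precision_at_x(run, x)
            pp[pid] = metrics
        per_pair[name] = pp
        all_runs = [runs[name][pid] for pid in sorted(runs[name])]
        s = {"map": mean_average_precision(all_runs)}
        for x in px:
            s[f"p@{x}"] = float(np.mean([pp[p][f"p@{x}"] for p in pp]))
            s[f"%p@{x}>0"] = 100.0 * fraction_pairs_positive(all_runs, x)
        summary[name] = s

    significance: dict[str, dict[str, SignificanceVerdict]] = {}
    ref_name = reference_ranker
    pair_order = sorted(runs[ref_name])
    for name in rankers:
        if name == ref_name:
            continue
        verdicts = {
            "ap": compare_significance(
                [per_pair[name][p]["ap"] for p in pair_order],
                [per_pair[ref_name][p]["ap"] for p in pair_order],
                alpha,
            )
        }
        for x in px:
            verdicts[f"p@{x}"] = compare_significance(
                [per_pair[name][p][f"p@{x}"] for p in pair_order],
                [per_pair[ref_name][p][f"p@{x}"] for p in pair_order],
                alpha,
            )
        significance[name] = verdicts

    log.append(f"elapsed={time.perf_counter() - t0:.2f}s")
    result = ExperimentResult(
        rankers=tuple(rankers),
        folds=folds,
        px=px,
        runs=runs,
        per_pair=per_pair,
        summary=summary,
        significance=significance,
        reference_ranker=ref_name,
        log=log,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def _write_outputs(out_dir: Path, result: ExperimentResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in result.rankers:
        safe = name.replace("+", "_plus_")
        ranker.write_ranked_run(
            out_dir / f"run_{safe}.tsv",
            {
                pid: list(
                    zip(
                        result.runs[name][pid].ranking,
                        _rank_scores(result.runs[name][pid]),
                    )
                )
                for pid in result.runs[name]
            },
        )
    write_metrics_report(out_dir / "per_pair_metrics.tsv", result.per_pair)
    with open(out_dir / "summary.tsv", "w", encoding="utf-8") as fh:
        metric_names = sorted(next(iter(result.summary.values())))
        fh.write("ranker\t" + "\t".join(metric_names) + "\n")
        for name in result.rankers:
            vals = "\t".join(
                format(result.summary[name][m], ".5f") for m in metric_names
            )
            fh.write(f"{name}\t{vals}\n")
    with open(out_dir / "significance.tsv", "w", encoding="utf-8") as fh:
        fh.write("ranker\tvs\tmetric\tp_ttest\tp_wilcoxon\tsignificant\n")
        for name in sorted(result.significance):
            for metric, v in sorted(result.significance[name].items()):
                fh.write(
                    f"{name}\t{result.reference_ranker}\t{metric}\t"
                    f"{v.p_ttest:.6g}\t{v.p_wilcoxon:.6g}\t{int(v.significant)}\n"
                )
    with open(out_dir / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(result.log) + "\n")


def _rank_scores(run: RankedRun) -> list[float]:
    # ranked runs store order only; emit the (deterministic) rank position
    # as a descending pseudo-score so the TSV is self-contained
    n = len(run.ranking)
    return [float(n - i) for i in range(n)]
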