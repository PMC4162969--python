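"""Pairwise linear learning-to-rank (RankingSVM-style).

Binary relevance reduces ranking to classification of difference
vectors: within every query, each (target, non-target) candidate pair
yields the feature difference and its mirror, and a linear large-margin
classifier (hinge loss, L2 penalty) is fitted on them.  The learned
weight vector then scores candidates directly; ties are broken by
ascending ref_id so ranked runs are reproducible.

Features are standardized with moments estimated on the training rows
only; constant features are excluded from the fit and their weights
forced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

__all__ = [
    "LinearRankModel",
    "train_pairwise",
    "rank_candidates",
    "build_integrative_features",
    "save_model",
    "load_model",
    "write_ranked_run",
]


@dataclass(frozen=True)
class LinearRankModel:
    """A linear scorer: score(x) = w . (x - mean) / scale."""

    weights: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray
    c_reg: float
    seed: int
    feature_names: tuple[str, ...] | None = None

    @property
    def dim(self) -> int:
        return self.weights.size

    def raw_weights(self) -> np.ndarray:
        """Weights expressed in the raw (unstandardized) feature space."""
        w = self.weights / self.scale
        w[self.constant_mask] = 0.0
        return w

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.dim}"
            )
        return ((X - self.mean) / self.scale) @ self.weights


def train_pairwise(
    training_set: Mapping[str, tuple[np.ndarray, np.ndarray]],
    c_reg: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
    feature_names: Sequence[str] | None = None,
) -> LinearRankModel:
    """Fit a linear ranker from per-query (features, binary labels) blocks.

    For each query, every (positive, negative) row pair contributes the
    standardized difference and its negation, labelled +1 / -1, and a
    no-intercept ``LinearSVC`` (hinge loss, L2 penalty, strength
    ``c_reg``) is fitted on the stacked differences.  Deterministic for a
    fixed seed.  Raises if no query holds both a positive and a negative
    row or if row dimensions disagree.
    """
    if not training_set:
        raise ValueError("empty training set")
    blocks = []
    dim = None
    for pair_id, (X, y) in training_set.items():
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise ValueError(f"query {pair_id!r}: features/labels length mismatch")
        if dim is None:
            dim = X.shape[1]
        elif X.shape[1] != dim:
            raise ValueError(
                f"query {pair_id!r}: dimension {X.shape[1]} != {dim}"
            )
        blocks.append((X, y.astype(bool)))

    all_rows = np.vstack([X for X, _ in blocks])
    mean = all_rows.mean(axis=0)
    scale = all_rows.std(axis=0)
    constant = scale < 1e-12
    scale = np.where(constant, 1.0, scale)

    diffs = []
    for X, y in blocks:
        pos = (X[y] - mean) / scale
        neg = (X[~y] - mean) / scale
        if len(pos) == 0 or len(neg) == 0:
            continue
        d = (pos[:, None, :] - neg[None, :, :]).reshape(-1, dim)
        diffs.append(d)
    if not diffs:
        raise ValueError(
            "vacuous training set: no query has both a target and a non-target"
        )
    D = np.vstack(diffs)
    if np.any(constant[: len(constant)]):
        D = D.copy()
        D[:, constant] = 0.0
    X_fit = np.vstack([D, -D])
    y_fit = np.concatenate([np.ones(len(D)), -np.ones(len(D))])

    svm = LinearSVC(
        loss="hinge",
        C=c_reg,
        tol=tol,
        fit_intercept=False,
        random_state=seed,
        max_iter=50_000,
    )
    # dual hinge may stop on the iteration cap rather than tol on
    # non-separable data; the solution is still deterministic for a seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svm.fit(X_fit, y_fit)
    weights = svm.coef_[0].astype(float).copy()
    weights[constant] = 0.0
    return LinearRankModel(
        weights=weights,
        mean=mean,
        scale=scale,
        constant_mask=constant,
        c_reg=c_reg,
        seed=seed,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def rank_candidates(
    model: LinearRankModel,
    pair_id: str,
    candidates: Sequence[tuple[str, np.ndarray]],
) -> list[tuple[str, float]]:
    """Score and order candidates: descending score, ties by ascending ref_id."""
    if not candidates:
        return []
    ref_ids = [ref_id for ref_id, _ in candidates]
    X = np.vstack([np.asarray(x, dtype=float) for _, x in candidates])
    scores = model.score(X)
    order = sorted(range(len(ref_ids)), key=lambda i: (-scores[i], ref_ids[i]))
    return [(ref_ids[i], float(scores[i])) for i in order]


def build_integrative_features(
    ref,
    pair,
    components: Sequence[Callable],
) -> np.ndarray:
    """Concatenate component outputs (scalars or vectors) in declared order.

    Each component is a callable ``f(ref, pair)`` returning a float or a
    1-D array; integrative rankers (e.g. BM25 + PosFreq) are built by
    listing the providers.
    """
    if not components:
        raise ValueError("integrative ranker needs at least one component")
    parts = [np.atleast_1d(np.asarray(c(ref, pair), dtype=float)) for c in components]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# plain-text serialization

def save_model(path: str | Path, model: LinearRankModel) -> None:
    def fmt(a: np.ndarray) -> str:
        return ",".join(repr(float(v)) for v in a)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"c_reg={model.c_reg!r}\n")
        fh.write(f"seed={model.seed}\n")
        fh.write(f"weights={fmt(model.weights)}\n")
        fh.write(f"mean={fmt(model.mean)}\n")
        fh.write(f"scale={fmt(model.scale)}\n")
        fh.write("constant=" + ",".join(str(int(b)) for b in model.constant_mask) + "\n")
        if model.feature_names is not None:
            fh.write("feature_names=" + ",".join(model.feature_names) + "\n")


def load_model(path: str | Path) -> LinearRankModel:
    fields: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                key, _, value = line.partition("=")
                fields[key] = value

    def arr(key: str) -> np.ndarray:
        return np.array([float(v) for v in fields[key].split(",")])

    names = fields.get("feature_names")
    return LinearRankModel(
        weights=arr("weights"),
        mean=arr("mean"),
        scale=arr("scale"),
        constant_mask=np.array([v == "1" for v in fields["constant"].split(",")]),
        c_reg=float(fields["c_reg"]),
        seed=int(fields["seed"]),
        feature_names=tuple(names.split(",")) if names else None,
    )


def write_ranked_run(
    path: str | Path,
    runs: Mapping[str, Sequence[tuple[str, float]]],
) -> None:
    """Write ranked runs as TSV: pair_id, rank, ref_id, score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pair_id\trank\tref_id\tscore\n")
        for pair_id in sorted(runs):
            for rank, (ref_id, score) in enumerate(runs[pair_id], start=1):
                fh.write(f"{pair_id}\t{rank}\t{ref_id}\t{score!r}\n")
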