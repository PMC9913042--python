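"""Retrieval evaluation: similarity matrices, QAP/AAP, hyperparameter search.

Retrieval quality of a run-similarity score is measured against metadata
labels (e.g. species) in two ways:

* **QAP** (per-query average precision): each run in turn is the query; the
  remaining runs are ranked by descending similarity and scored by average
  precision against the "same label" relevance; QAP is the mean over queries.
* **AAP** (aggregate average precision): all upper-triangle run pairs are
  pooled into a single descending-score list and average precision is
  computed once, with "same label" relevance per pair.

Both depend only on the *ranking*, so they are invariant under any strictly
monotone transform of the scores.  Ties are broken deterministically by
ascending run identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import Ms1MatchError, ParameterError
from .features import Run
from .matcher import DEFAULT_MAX_EDGES, score_pair
from .objective import ObjectiveParams

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class SimilarityMatrix:
    """Symmetric run-by-run score matrix; the diagonal is never ranked."""

    run_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.run_ids)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (n, n):
            raise ParameterError(
                f"scores must be {n}x{n} for {n} run ids, got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ParameterError("score matrix contains non-finite entries")
        if not np.allclose(self.scores, self.scores.T):
            raise ParameterError("score matrix is not symmetric")

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("run_id\t" + "\t".join(self.run_ids) + "\n")
            for rid, row in zip(self.run_ids, self.scores):
                fh.write(rid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(run_ids=[str(c) for c in df.columns], scores=df.to_numpy(dtype=np.float64))


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``run_id<TAB>label`` file (no header required)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["run_id", "label"],
                     dtype=str)
    if len(df) and tuple(df.iloc[0]) == ("run_id", "label"):
        df = df.iloc[1:]
    return dict(zip(df["run_id"], df["label"]))


def pairwise_score_matrix(
    runs: Sequence[Run],
    p: ObjectiveParams,
    score_fn: Callable[[Run, Run], float] | None = None,
    max_edges: int | None = DEFAULT_MAX_EDGES,
) -> SimilarityMatrix:
    """Assemble the symmetric pairwise matrix, computing each pair once.

    *score_fn* overrides the default matching score (e.g. with a baseline);
    it must itself be symmetric.
    """
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate run_id in dataset")
    if score_fn is None:
        score_fn = lambda a, b: score_pair(a, b, p, max_edges=max_edges).score
    n = len(runs)
    scores = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i, n):
            s = float(score_fn(runs[i], runs[j]))
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(run_ids=ids, scores=scores)


def average_precision(relevance: Sequence[int]) -> float:
    """Average precision of a ranked 0/1 relevance list.

    AP = Σ_k P_k (R_k − R_{k−1}) where P_k and R_k are precision and recall
    after the top k items — equivalently the mean of P_k over relevant ranks.
    """
    rel = np.asarray(relevance, dtype=np.int64)
    if rel.ndim != 1 or not np.isin(rel, (0, 1)).all():
        raise ParameterError("relevance must be a 1-D sequence of 0/1")
    n_rel = int(rel.sum())
    if n_rel == 0:
        raise ParameterError("average precision undefined: no relevant items")
    cum = np.cumsum(rel)
    ranks = np.arange(1, rel.size + 1)
    return float((cum[rel == 1] / ranks[rel == 1]).sum() / n_rel)


def _check_labels(run_ids: Sequence[str], labels: Mapping[str, str]) -> None:
    missing = [r for r in run_ids if r not in labels]
    if missing:
        raise Ms1MatchError(f"unlabeled run(s): {', '.join(missing)}")


def qap(m: SimilarityMatrix, labels: Mapping[str, str]) -> float:
    """Per-query average precision, mean over all usable queries.

    Each query ranks the other runs by descending score (ties by ascending
    run_id).  Queries whose label occurs nowhere else are skipped with a
    warning, since average precision is undefined for them.
    """
    _check_labels(m.run_ids, labels)
    if len(m.run_ids) < 2:
        raise ParameterError("need at least two runs")
    aps = []
    for qi, q in enumerate(m.run_ids):
        others = [(j, m.run_ids[j]) for j in range(len(m.run_ids)) if j != qi]
        rel_total = sum(labels[rid] == labels[q] for _, rid in others)
        if rel_total == 0:
            logger.warning("query %r skipped: no other run shares its label", q)
            continue
        ranked = sorted(others, key=lambda jr: (-m.scores[qi, jr[0]], jr[1]))
        relevance = [1 if labels[rid] == labels[q] else 0 for _, rid in ranked]
        aps.append(average_precision(relevance))
    if not aps:
        raise Ms1MatchError("no query has a same-label counterpart")
    return float(np.mean(aps))


def aap(m: SimilarityMatrix, labels: Mapping[str, str]) -> float:
    """Aggregate average precision over the globally sorted upper triangle."""
    _check_labels(m.run_ids, labels)
    if len(m.run_ids) < 2:
        raise ParameterError("need at least two runs")
    pairs = []
    for i in range(len(m.run_ids)):
        for j in range(i + 1, len(m.run_ids)):
            pairs.append((m.scores[i, j], m.run_ids[i], m.run_ids[j]))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    relevance = [1 if labels[a] == labels[b] else 0 for _, a, b in pairs]
    if sum(relevance) == 0:
        raise Ms1MatchError("no same-label pair exists")
    return average_precision(relevance)


# ---------------------------------------------------------------------------
# random hyperparameter search

#: Default search ranges; λ1–λ4 are always drawn uniformly on the simplex.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "n_features": (100, 5000),        # uniform integer
    "delta1_ppm": (1.0, 20.0),        # log-uniform
    "alpha": (0.01, 100.0),           # log-uniform
    "beta": (0.01, 100.0),            # log-uniform
    "gamma": (0.01, 100.0),           # log-uniform
}


def _draw_params(rng: np.random.Generator, ranges: Mapping[str, tuple[float, float]]) -> ObjectiveParams:
    def log_u(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    n = int(rng.integers(int(ranges["n_features"][0]), int(ranges["n_features"][1]) + 1))
    lam = rng.uniform(size=4)
    lam = lam / lam.sum()
    # renormalize exactly so the simplex invariant holds to 1e-9
    lam[3] = max(1.0 - float(lam[0] + lam[1] + lam[2]), 0.0)
    return ObjectiveParams(
        n_features=n,
        delta1_ppm=log_u(*ranges["delta1_ppm"]),
        lambda1=float(lam[0]), lambda2=float(lam[1]),
        lambda3=float(lam[2]), lambda4=float(lam[3]),
        alpha=log_u(*ranges["alpha"]),
        beta=log_u(*ranges["beta"]),
        gamma=log_u(*ranges["gamma"]),
    )


def random_search(
    runs: Sequence[Run],
    labels: Mapping[str, str],
    n_draws: int,
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    max_edges: int | None = DEFAULT_MAX_EDGES,
) -> pd.DataFrame:
    """Random search over the nine hyperparameters, scored by QAP (and AAP).

    Draws *n_draws* parameterizations (λ on the simplex, scale parameters
    log-uniform), computes the full pairwise matrix for each, and returns a
    DataFrame sorted by descending QAP.  Reproducible for a fixed *seed*.
    """
    if n_draws < 1:
        raise ParameterError(f"n_draws must be >= 1, got {n_draws}")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(n_draws):
        p = _draw_params(rng, ranges)
        matrix = pairwise_score_matrix(runs, p, max_edges=max_edges)
        rows.append({
            "draw": draw,
            "n_features": p.n_features,
            "delta1_ppm": p.delta1_ppm,
            "lambda1": p.lambda1, "lambda2": p.lambda2,
            "lambda3": p.lambda3, "lambda4": p.lambda4,
            "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma,
            "qap": qap(matrix, labels),
            "aap": aap(matrix, labels),
        })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    return df.sort_values(["qap", "draw"], ascending=[False, True], ignore_index=True)


def write_search_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a search table with a ``# seed=`` header line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# seed={df.attrs.get('seed', 'unknown')}\n")
        df.to_csv(fh, sep="\t", index=False)
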