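"""Matching selection and the final run-pair similarity score.

The matching problem: choose A ⊆ E with every feature on either side incident
to at most one chosen edge (the intersection of two partition matroids),
maximizing the normalized objective M(A) = Σ_i λ_i M_i(A)/M_i(E).  Because M4
is supermodular this is solved approximately by the greedy algorithm:
repeatedly add the feasible edge with the largest marginal gain

    Δ(e | A) = Σ_{i=1..3} λ_i m_i(e)/M_i(E) + λ4 (1 + 2 Σ_{e'∈A} m4(e, e'))/M4(E)

(the 1 is the new diagonal entry, the factor 2 the two symmetric off-diagonal
rows of the pair-affinity matrix).  All entries are nonnegative, so greedy
runs until no feasible edge remains.  Ties are broken by the canonical edge
order, which is invariant under swapping the two runs — the returned score is
therefore exactly symmetric.

The final pair score un-normalizes the matching value by the run-pair
constant Σ_j λ_j M_j(E):  S = (Σ_j λ_j M_j(E)) · M(A).  This keeps the λ
weights interpretable while calibrating scores across run pairs of different
sizes.

A brute-force enumerator over all feasible matchings (guarded to |E| ≤ 20)
serves as an exact oracle for testing greedy's approximation quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyRunError, ParameterError
from .features import Run, prepare_run
from .graph import BipartiteGraph, Edge, build_edges
from .objective import (
    ObjectiveParams,
    TermBreakdown,
    diag_arrays,
    m4_cross,
    m4_total,
    normalized_value,
    term_totals,
)

#: Default cap on |E|; beyond it only the lowest-ppm edges are kept.
DEFAULT_MAX_EDGES = 20_000

_BRUTE_FORCE_LIMIT = 20


@dataclass(frozen=True, slots=True)
class Matching:
    """A degree-constrained edge subset with its normalized objective value."""

    edges: tuple[Edge, ...]
    edge_indices: tuple[int, ...]
    objective_value: float

    def __len__(self) -> int:
        return len(self.edge_indices)


@dataclass(frozen=True, slots=True)
class ScoreBreakdown:
    """The calibrated pair score S with everything needed to recompute it.

    ``score = leading_factor * matching.objective_value`` where
    ``leading_factor = Σ_j λ_j M_j(E)``.
    """

    score: float
    matching: Matching
    terms_A: TermBreakdown
    terms_E: TermBreakdown
    leading_factor: float


def _empty_matching() -> Matching:
    return Matching(edges=(), edge_indices=(), objective_value=0.0)


def _check_feasible(g: BipartiteGraph, idx: np.ndarray) -> None:
    u = g.u_index[idx]
    v = g.v_index[idx]
    if len(np.unique(u)) != len(u) or len(np.unique(v)) != len(v):
        raise AssertionError("matching violates degree constraints")


def greedy_match(g: BipartiteGraph, p: ObjectiveParams) -> Matching:
    """Greedy supermodular maximization under the two-sided degree-1 constraint."""
    m = g.n_edges
    if m == 0:
        return _empty_matching()

    m1a, m2a, m3a = diag_arrays(g, p)
    norm = (float(m1a.sum()), float(m2a.sum()), float(m3a.sum()))
    m4e = m4_total(g, p) if p.lambda4 > 0 else 0.0

    diag_gain = np.zeros(m, dtype=np.float64)
    for lam, arr, me in zip(p.lambdas[:3], (m1a, m2a, m3a), norm):
        if lam > 0 and me > 0:
            diag_gain += lam * arr / me
    use_m4 = p.lambda4 > 0 and m4e > 0

    s4 = np.zeros(m, dtype=np.float64)  # Σ_{e' selected} m4(e, e') per candidate
    feasible = np.ones(m, dtype=bool)
    selected: list[int] = []
    while feasible.any():
        if use_m4:
            gains = diag_gain + p.lambda4 * (1.0 + 2.0 * s4) / m4e
        else:
            gains = diag_gain
        gains = np.where(feasible, gains, -np.inf)
        j = int(np.argmax(gains))  # first maximum -> lowest canonical index
        selected.append(j)
        feasible &= (g.u_index != g.u_index[j]) & (g.v_index != g.v_index[j])
        if use_m4 and feasible.any():
            s4 += m4_cross(g, p, j)

    idx = np.array(selected, dtype=np.int64)
    _check_feasible(g, idx)
    tb = term_totals(idx, g, p)
    edges = tuple(g.edges[k] for k in selected)
    return Matching(edges=edges, edge_indices=tuple(selected),
                    objective_value=normalized_value(tb, p))


def brute_force_match(g: BipartiteGraph, p: ObjectiveParams) -> Matching:
    """Exact maximizer over all feasible matchings; |E| must be ≤ 20.

    Enumerates every A ⊆ E satisfying both degree constraints and returns the
    maximizer of the normalized objective; exact ties are broken by the
    lexicographically smallest tuple of canonical edge indices.
    """
    m = g.n_edges
    if m > _BRUTE_FORCE_LIMIT:
        raise ParameterError(
            f"brute force enumeration limited to {_BRUTE_FORCE_LIMIT} edges, got {m}; "
            "shrink the instance"
        )
    if m == 0:
        return _empty_matching()

    u_idx, v_idx = g.u_index, g.v_index
    best_val = 0.0
    best: tuple[int, ...] = ()

    def consider(sel: tuple[int, ...]) -> None:
        nonlocal best_val, best
        tb = term_totals(np.array(sel, dtype=np.int64), g, p)
        val = normalized_value(tb, p)
        if val > best_val or (val == best_val and sel < best):
            best_val, best = val, sel

    def recurse(start: int, sel: tuple[int, ...], used_u: set, used_v: set) -> None:
        if sel:
            consider(sel)
        for k in range(start, m):
            uu, vv = int(u_idx[k]), int(v_idx[k])
            if uu in used_u or vv in used_v:
                continue
            recurse(k + 1, sel + (k,), used_u | {uu}, used_v | {vv})

    recurse(0, (), set(), set())
    if not best:
        return _empty_matching()
    idx = np.array(best, dtype=np.int64)
    _check_feasible(g, idx)
    return Matching(edges=tuple(g.edges[k] for k in best), edge_indices=best,
                    objective_value=best_val)


def score_graph(g: BipartiteGraph, p: ObjectiveParams) -> ScoreBreakdown:
    """Greedy matching plus the calibrated score for an already-built graph."""
    if g.n_edges == 0:
        empty = TermBreakdown(0.0, 0.0, 0.0, 0.0, normalizers=(0.0, 0.0, 0.0, 0.0))
        return ScoreBreakdown(score=0.0, matching=_empty_matching(),
                              terms_A=empty, terms_E=empty, leading_factor=0.0)
    matching = greedy_match(g, p)
    terms_A = term_totals(np.array(matching.edge_indices, dtype=np.int64), g, p)
    terms_E = TermBreakdown(*terms_A.normalizers, normalizers=terms_A.normalizers)
    leading = sum(lam * me for lam, me in zip(p.lambdas, terms_A.normalizers))
    return ScoreBreakdown(
        score=leading * matching.objective_value,
        matching=matching,
        terms_A=terms_A,
        terms_E=terms_E,
        leading_factor=leading,
    )


def score_pair(
    run_a: Run,
    run_b: Run,
    p: ObjectiveParams,
    max_edges: int | None = DEFAULT_MAX_EDGES,
) -> ScoreBreakdown:
    """Full pipeline for a pair of raw runs: top-N, normalize, match, score.

    Deterministic for fixed inputs and parameters, and exactly symmetric in
    its two run arguments.  Returns score 0 when no valid edges exist.
    """
    if not run_a.features or not run_b.features:
        empty = run_a.run_id if not run_a.features else run_b.run_id
        raise EmptyRunError(f"run {empty!r} has no features")
    a = prepare_run(run_a, p.n_features)
    b = prepare_run(run_b, p.n_features)
    g = build_edges(a, b, p.delta1_ppm, max_edges=max_edges)
    return score_graph(g, p)
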