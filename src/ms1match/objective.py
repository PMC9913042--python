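"""The four-term matching objective: entries, totals and normalizers.

The score of an edge set A is a convex combination of four set functions:

* M1(A) = |A|                       — rewards many matched features;
* M2(A) = Σ mean normalized intensity of each edge's endpoints
                                    — rewards matching intense features;
* M3(A) = Σ exp(−α·|Δt(e)|)         — rewards small normalized-RT shifts;
* M4(A) = Σ over *ordered pairs* (e1, e2) ∈ A×A of a pairwise affinity
  m4(e1, e2) = exp(−β·|Δt(e1) − Δt(e2)|) · exp(−γ·(|t_u(e1) − t_u(e2)| +
  |t_v(e1) − t_v(e2)|)/2), with m4(e, e) = 1 on the diagonal — rewards
  *coherent* sets of edges whose RT shifts agree and whose features elute
  close together, which is what distinguishes a systematic chromatography
  shift from coincidental m/z collisions.

M1–M3 are modular (sums of per-edge weights); M4 is supermodular: the gain of
adding an edge grows with the edges already selected.  Each term is normalized
by its value on the full edge set E, so the λ weights are comparable across
run pairs of very different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .graph import BipartiteGraph, Edge

_M4_BLOCK = 2048  # row block for the O(|E|^2) pair-affinity sums


@dataclass(frozen=True, slots=True)
class ObjectiveParams:
    """The nine hyperparameters of the matching score.

    ``n_features`` (N) caps each run at its N most intense features;
    ``delta1_ppm`` (δ1) is the edge m/z tolerance in ppm; λ1–λ4 weight the
    four terms and must lie in [0, 1] and sum to 1; ``alpha`` is the M3 decay
    per unit normalized-RT shift; ``beta`` and ``gamma`` are the M4 decays on
    shift disagreement and on same-run RT distance.

    Defaults are the best-performing configuration from a random search of
    2500 parameterizations: N = 4000, δ1 = 4 ppm, λ4 = 0.9.
    """

    n_features: int = 4000
    delta1_ppm: float = 4.0
    lambda1: float = 0.025
    lambda2: float = 0.025
    lambda3: float = 0.05
    lambda4: float = 0.9
    alpha: float = 1.0
    beta: float = 10.0
    gamma: float = 10.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ParameterError(f"n_features must be >= 1, got {self.n_features}")
        if self.delta1_ppm <= 0:
            raise ParameterError(f"delta1_ppm must be positive, got {self.delta1_ppm}")
        lam = self.lambdas
        if any(not (0.0 <= l <= 1.0) for l in lam):
            raise ParameterError(f"each lambda must lie in [0, 1], got {lam}")
        if abs(sum(lam) - 1.0) > 1e-9:
            raise ParameterError(f"lambdas must sum to 1, got sum {sum(lam)!r}")
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @property
    def lambdas(self) -> tuple[float, float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3, self.lambda4)

    def without_supermodular(self) -> "ObjectiveParams":
        """Modular variant: λ4 = 0, its mass redistributed over λ1–λ3."""
        rest = self.lambda1 + self.lambda2 + self.lambda3
        if rest > 0:
            s = 1.0 / rest
            return replace(self, lambda1=self.lambda1 * s, lambda2=self.lambda2 * s,
                           lambda3=self.lambda3 * s, lambda4=0.0)
        return replace(self, lambda1=1 / 3, lambda2=1 / 3, lambda3=1 / 3, lambda4=0.0)

    def single_term(self, i: int) -> "ObjectiveParams":
        """Variant using only term *i* (1-based), e.g. the M4-only score."""
        if i not in (1, 2, 3, 4):
            raise ParameterError(f"term index must be 1..4, got {i}")
        lam = [0.0, 0.0, 0.0, 0.0]
        lam[i - 1] = 1.0
        return replace(self, lambda1=lam[0], lambda2=lam[1], lambda3=lam[2], lambda4=lam[3])


@dataclass(frozen=True, slots=True)
class TermBreakdown:
    """Per-term totals M1..M4 over an edge set, plus the full-set normalizers."""

    m1: float
    m2: float
    m3: float
    m4: float
    normalizers: tuple[float, float, float, float]

    @property
    def totals(self) -> tuple[float, float, float, float]:
        return (self.m1, self.m2, self.m3, self.m4)


# ---------------------------------------------------------------------------
# scalar entry functions (reference semantics; vectorized forms below)

def diag_entry(e: Edge, g: BipartiteGraph, p: ObjectiveParams) -> tuple[float, float, float]:
    """Diagonal contributions (m1, m2, m3) of a single edge; each in [0, 1]."""
    m1 = 1.0
    m2 = (e.intensity_u + e.intensity_v) / 2.0
    m3 = float(np.exp(-p.alpha * abs(e.rt_shift)))
    return (m1, m2, m3)


def pair_entry(e1: Edge, e2: Edge, p: ObjectiveParams) -> float:
    """Pairwise affinity m4(e1, e2) in [0, 1]; 1 on the diagonal; symmetric."""
    if e1.u_index == e2.u_index and e1.v_index == e2.v_index:
        return 1.0
    d_shift = abs(e1.rt_shift - e2.rt_shift)
    d_pos = (abs(e1.rt_u - e2.rt_u) + abs(e1.rt_v - e2.rt_v)) / 2.0
    return float(np.exp(-(p.beta * d_shift + p.gamma * d_pos)))


# ---------------------------------------------------------------------------
# vectorized internals

def diag_arrays(g: BipartiteGraph, p: ObjectiveParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(m1, m2, m3) arrays over the graph's edges in canonical order."""
    m1 = np.ones(g.n_edges, dtype=np.float64)
    m2 = (g.int_u + g.int_v) / 2.0
    m3 = np.exp(-p.alpha * np.abs(g.rt_shift))
    return m1, m2, m3

def m4_cross(g: BipartiteGraph, p: ObjectiveParams, j: int,
             idx: np.ndarray | None = None) -> np.ndarray:
    """m4 affinity of edge *j* against every edge in *idx* (default: all)."""
    if idx is None:
        shift, tu, tv = g.rt_shift, g.rt_u, g.rt_v
    else:
        shift, tu, tv = g.rt_shift[idx], g.rt_u[idx], g.rt_v[idx]
    d_shift = np.abs(shift - g.rt_shift[j])
    d_pos = (np.abs(tu - g.rt_u[j]) + np.abs(tv - g.rt_v[j])) / 2.0
    return np.exp(-(p.beta * d_shift + p.gamma * d_pos))


def m4_total(g: BipartiteGraph, p: ObjectiveParams, idx: np.ndarray | None = None) -> float:
    """Σ over ordered pairs of m4, diagonal included; blockwise in O(m^2)."""
    if idx is None:
        shift, tu, tv = g.rt_shift, g.rt_u, g.rt_v
    else:
        shift, tu, tv = g.rt_shift[idx], g.rt_u[idx], g.rt_v[idx]
    m = shift.size
    if m == 0:
        return 0.0
    total = 0.0
    for i0 in range(0, m, _M4_BLOCK):
        sl = slice(i0, min(i0 + _M4_BLOCK, m))
        d_shift = np.abs(shift[sl, None] - shift[None, :])
        d_pos = (np.abs(tu[sl, None] - tu[None, :]) + np.abs(tv[sl, None] - tv[None, :])) / 2.0
        total += float(np.exp(-(p.beta * d_shift + p.gamma * d_pos)).sum())
    return total


def _as_indices(edge_set, g: BipartiteGraph) -> np.ndarray:
    """Accept an index array or a collection of Edge objects."""
    items = list(edge_set)
    if items and isinstance(items[0], Edge):
        lookup = {(int(u), int(v)): k for k, (u, v) in enumerate(zip(g.u_index, g.v_index))}
        return np.array([lookup[(e.u_index, e.v_index)] for e in items], dtype=np.int64)
    return np.asarray(items, dtype=np.int64)


def term_totals(edge_set: Sequence, g: BipartiteGraph, p: ObjectiveParams) -> TermBreakdown:
    """Totals M1..M4 over *edge_set* plus the normalizers Mi(E).

    *edge_set* may be any subset of E (including E itself; matching
    constraints are not required here) given either as integer indices into
    the canonical edge order or as :class:`Edge` objects.
    """
    idx = _as_indices(edge_set, g)
    m1a, m2a, m3a = diag_arrays(g, p)
    totals = (
        float(m1a[idx].sum()),
        float(m2a[idx].sum()),
        float(m3a[idx].sum()),
        m4_total(g, p, idx),
    )
    normalizers = (
        float(m1a.sum()),
        float(m2a.sum()),
        float(m3a.sum()),
        m4_total(g, p),
    )
    return TermBreakdown(*totals, normalizers=normalizers)


def normalized_value(tb: TermBreakdown, p: ObjectiveParams) -> float:
    """M(A) = Σ_i λ_i M_i(A)/M_i(E), with 0/0 := 0 for degenerate terms."""
    val = 0.0
    for lam, ma, me in zip(p.lambdas, tb.totals, tb.normalizers):
        if lam > 0 and me > 0:
            val += lam * ma / me
    return val
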