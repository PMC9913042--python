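"""Run-pair bipartite graphs of charge- and ppm-compatible feature pairs.

Two MS1 features from different runs are connected by an edge when their
charges are equal and their m/z values agree within a tolerance ``delta1``
expressed in parts per million of the *mean* of the two m/z values (boundary
inclusive).  Degree constraints are NOT applied here: a feature may appear in
many edges of the full edge set E; matchings are selected later.

Edges are kept in a canonical order that is invariant under swapping the two
runs (sort key = the unordered pair of endpoint feature keys), which is what
makes the final pair score exactly symmetric, ties included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .features import Run, feature_arrays

logger = logging.getLogger(__name__)


def ppm_difference(mz_u: float, mz_v: float) -> float:
    """Relative m/z difference in ppm, against the mean of the two values.

    Symmetric in its arguments: ``|mz_v - mz_u| / ((mz_u + mz_v)/2) * 1e6``.
    """
    if not (mz_u > 0 and mz_v > 0 and math.isfinite(mz_u) and math.isfinite(mz_v)):
        raise ParameterError(f"m/z values must be positive and finite, got {mz_u}, {mz_v}")
    return abs(mz_v - mz_u) / ((mz_v + mz_u) / 2.0) * 1e6


@dataclass(frozen=True, slots=True)
class Edge:
    """A ppm/charge-valid feature pair between runs U and V.

    ``rt_shift`` is signed: ``rt_norm(v) - rt_norm(u)``.  The normalized
    endpoint values are carried on the edge so that objective entries can be
    evaluated without going back to the graph.
    """

    u_index: int
    v_index: int
    ppm_delta: float
    rt_shift: float
    rt_u: float
    rt_v: float
    intensity_u: float
    intensity_v: float
    charge: int


@dataclass(slots=True)
class BipartiteGraph:
    """Two runs plus the full set E of valid edges, in canonical order.

    Edge attributes are stored as parallel numpy arrays (``u_index``,
    ``v_index``, ``ppm_delta``, ``rt_shift``, ``rt_u``, ``rt_v``, ``int_u``,
    ``int_v``, ``charge``); :attr:`edges` materializes :class:`Edge` objects
    on demand.
    """

    run_u: Run
    run_v: Run
    delta1_ppm: float
    u_index: np.ndarray
    v_index: np.ndarray
    ppm_delta: np.ndarray
    rt_shift: np.ndarray
    rt_u: np.ndarray
    rt_v: np.ndarray
    int_u: np.ndarray
    int_v: np.ndarray
    charge: np.ndarray
    _edges: tuple | None = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return int(self.u_index.size)

    @property
    def edges(self) -> tuple[Edge, ...]:
        if self._edges is None:
            self._edges = tuple(
                Edge(
                    u_index=int(self.u_index[k]),
                    v_index=int(self.v_index[k]),
                    ppm_delta=float(self.ppm_delta[k]),
                    rt_shift=float(self.rt_shift[k]),
                    rt_u=float(self.rt_u[k]),
                    rt_v=float(self.rt_v[k]),
                    intensity_u=float(self.int_u[k]),
                    intensity_v=float(self.int_v[k]),
                    charge=int(self.charge[k]),
                )
                for k in range(self.n_edges)
            )
        return self._edges

    def write_edge_list(self, path: str | Path) -> None:
        """Debug export: tab-separated u_index, v_index, ppm_delta, rt_shift."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("u_index\tv_index\tppm_delta\trt_shift\n")
            for k in range(self.n_edges):
                fh.write(
                    f"{int(self.u_index[k])}\t{int(self.v_index[k])}\t"
                    f"{self.ppm_delta[k]!r}\t{self.rt_shift[k]!r}\n"
                )


def _feature_key(arrs: dict[str, np.ndarray], i: int) -> tuple:
    # Raw-value key; identical for identical features on either side, which
    # makes the canonical edge order invariant under swapping the two runs.
    return (arrs["mz"][i], arrs["rt"][i], arrs["intensity"][i], arrs["charge"][i])


def build_edges(
    run_u: Run,
    run_v: Run,
    delta1_ppm: float,
    max_edges: int | None = None,
) -> BipartiteGraph:
    """Build the full edge set E between two normalized runs.

    Edges are exactly the feature pairs with equal charge and
    :func:`ppm_difference` <= *delta1_ppm* (inclusive).  If *max_edges* is
    given and exceeded, only the lowest-ppm edges are kept (stable under the
    canonical order) with a logged warning; the truncation is symmetric under
    swapping the runs.
    """
    if delta1_ppm <= 0:
        raise ParameterError(f"delta1_ppm must be positive, got {delta1_ppm}")
    for run in (run_u, run_v):
        if not run.is_normalized:
            raise ParameterError(
                f"run {run.run_id!r} must be normalized before graph construction"
            )

    au = feature_arrays(run_u)
    av = feature_arrays(run_v)
    t = delta1_ppm * 1e-6

    pairs_u: list[int] = []
    pairs_v: list[int] = []
    charges = np.intersect1d(np.unique(au["charge"]), np.unique(av["charge"]))
    for z in charges:
        iu = np.flatnonzero(au["charge"] == z)
        iv = np.flatnonzero(av["charge"] == z)
        mzu = au["mz"][iu]
        mzv = av["mz"][iv]
        order_v = np.argsort(mzv, kind="stable")
        mzv_sorted = mzv[order_v]
        # |mv - mu| <= t*(mu+mv)/2  <=>  mu*(1-t/2)/(1+t/2) <= mv <= mu*(1+t/2)/(1-t/2)
        lo = mzu * (1 - t / 2) / (1 + t / 2) * (1 - 1e-12)
        hi = mzu * (1 + t / 2) / (1 - t / 2) * (1 + 1e-12)
        starts = np.searchsorted(mzv_sorted, lo, side="left")
        stops = np.searchsorted(mzv_sorted, hi, side="right")
        for k in range(iu.size):
            for j in order_v[starts[k]:stops[k]]:
                mu, mv = mzu[k], mzv[j]
                if abs(mv - mu) / ((mv + mu) / 2.0) * 1e6 <= delta1_ppm:
                    pairs_u.append(int(iu[k]))
                    pairs_v.append(int(iv[j]))

    u_idx = np.array(pairs_u, dtype=np.int64)
    v_idx = np.array(pairs_v, dtype=np.int64)

    # Canonical order: unordered pair of endpoint keys, smaller key first.
    keys = [
        tuple(sorted((_feature_key(au, int(u)), _feature_key(av, int(v)))))
        for u, v in zip(u_idx, v_idx)
    ]
    order = sorted(range(len(keys)), key=keys.__getitem__)
    u_idx = u_idx[order] if len(order) else u_idx
    v_idx = v_idx[order] if len(order) else v_idx

    ppm = np.array(
        [ppm_difference(au["mz"][u], av["mz"][v]) for u, v in zip(u_idx, v_idx)],
        dtype=np.float64,
    )

    if max_edges is not None and u_idx.size > max_edges:
        logger.warning(
            "edge set between %r and %r has %d edges, capping to the %d lowest-ppm",
            run_u.run_id, run_v.run_id, u_idx.size, max_edges,
        )
        keep = np.sort(np.argsort(ppm, kind="stable")[:max_edges])
        u_idx, v_idx, ppm = u_idx[keep], v_idx[keep], ppm[keep]

    rt_u = au["rt_norm"][u_idx]
    rt_v = av["rt_norm"][v_idx]
    return BipartiteGraph(
        run_u=run_u,
        run_v=run_v,
        delta1_ppm=float(delta1_ppm),
        u_index=u_idx,
        v_index=v_idx,
        ppm_delta=ppm,
        rt_shift=rt_v - rt_u,
        rt_u=rt_u,
        rt_v=rt_v,
        int_u=au["intensity_norm"][u_idx],
        int_v=av["intensity_norm"][v_idx],
        charge=au["charge"][u_idx],
    )
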