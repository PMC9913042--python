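"""Baseline run-similarity measures: binned co-occurrence and soft kernels.

These are the simple alternatives the matching score is compared against:

* **Binned** similarities drop each feature into an (m/z bin, RT bin, charge)
  cell and aggregate the two runs' per-cell counts with one of four rules
  (indicator / product / min / max).  With ``n_rt_bins = 1`` retention time
  is ignored.  Hard bin boundaries make these scores sensitive to systematic
  RT shifts between experiments (edge effects) — the phenomenon the matching
  score's within-run normalization is designed to avoid.
* **Continuous** similarity replaces bins with Gaussian kernels on the ppm
  m/z distance (and optionally on the normalized-RT distance) summed over all
  same-charge feature pairs within a 3σ ppm window.

The ``max`` aggregator is implemented for completeness but excluded from
default reports due to poor retrieval performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .features import Run, feature_arrays

AGGREGATORS = ("indicator", "product", "min", "max")

#: Aggregators included in default reports ("max" performs poorly).
DEFAULT_AGGREGATORS = ("indicator", "product", "min")


@dataclass(slots=True)
class BinGrid:
    """Feature counts per (m/z bin, RT bin, charge) cell for one run."""

    mz_bin_width: float
    n_rt_bins: int
    counts: dict[tuple[int, int, int], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def bin_run(run: Run, mz_bin_width: float, n_rt_bins: int) -> BinGrid:
    """Accumulate a normalized run's features onto the bin grid.

    ``mz_bin = floor(mz / width)``; the RT bin uses ``rt_norm`` and clamps
    the right boundary (rt_norm = 1.0 lands in the last bin).
    """
    if mz_bin_width <= 0:
        raise ParameterError(f"mz_bin_width must be positive, got {mz_bin_width}")
    if n_rt_bins < 1:
        raise ParameterError(f"n_rt_bins must be >= 1, got {n_rt_bins}")
    if not run.is_normalized:
        raise ParameterError(f"run {run.run_id!r} must be normalized before binning")
    grid = BinGrid(mz_bin_width=mz_bin_width, n_rt_bins=n_rt_bins)
    for f in run.features:
        key = (
            int(math.floor(f.mz / mz_bin_width)),
            min(int(math.floor(f.rt_norm * n_rt_bins)), n_rt_bins - 1),
            f.charge,
        )
        grid.counts[key] = grid.counts.get(key, 0) + 1
    return grid


def binned_similarity(a: BinGrid, b: BinGrid, aggregator: str) -> float:
    """Aggregate two grids' co-occupied cells; symmetric for all aggregators."""
    if aggregator not in AGGREGATORS:
        raise ParameterError(f"aggregator must be one of {AGGREGATORS}, got {aggregator!r}")
    if a.mz_bin_width != b.mz_bin_width or a.n_rt_bins != b.n_rt_bins:
        raise ParameterError("grids were built with different binning parameters")
    if aggregator == "max":
        keys = set(a.counts) | set(b.counts)
        return float(sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in keys))
    keys = set(a.counts) & set(b.counts)
    if aggregator == "indicator":
        return float(len(keys))
    if aggregator == "product":
        return float(sum(a.counts[k] * b.counts[k] for k in keys))
    return float(sum(min(a.counts[k], b.counts[k]) for k in keys))


def binned_run_similarity(
    run_a: Run,
    run_b: Run,
    aggregator: str,
    mz_bin_width: float = 0.01,
    n_rt_bins: int = 1,
) -> float:
    """Convenience wrapper: bin both normalized runs and aggregate."""
    ga = bin_run(run_a, mz_bin_width, n_rt_bins)
    gb = bin_run(run_b, mz_bin_width, n_rt_bins)
    return binned_similarity(ga, gb, aggregator)


def continuous_similarity(
    run_a: Run,
    run_b: Run,
    sigma_ppm: float = 2.0,
    sigma_rt: float = 0.05,
    use_rt: bool = False,
) -> float:
    """Gaussian-kernel similarity over same-charge feature pairs.

    Sums ``exp(-ppm²/(2σ_ppm²))`` — times ``exp(-Δrt_norm²/(2σ_rt²))`` when
    *use_rt* — over every same-charge pair within 3σ_ppm.  Symmetric.
    """
    if sigma_ppm <= 0 or sigma_rt <= 0:
        raise ParameterError("sigma_ppm and sigma_rt must be positive")
    for run in (run_a, run_b):
        if not run.is_normalized:
            raise ParameterError(f"run {run.run_id!r} must be normalized")
    aa = feature_arrays(run_a)
    ab = feature_arrays(run_b)
    total = 0.0
    for z in np.intersect1d(np.unique(aa["charge"]), np.unique(ab["charge"])):
        ia = np.flatnonzero(aa["charge"] == z)
        ib = np.flatnonzero(ab["charge"] == z)
        for i in ia:
            mz_i = aa["mz"][i]
            ppm = np.abs(ab["mz"][ib] - mz_i) / ((ab["mz"][ib] + mz_i) / 2.0) * 1e6
            near = ppm <= 3.0 * sigma_ppm
            if not near.any():
                continue
            k = np.exp(-ppm[near] ** 2 / (2.0 * sigma_ppm**2))
            if use_rt:
                drt = ab["rt_norm"][ib][near] - aa["rt_norm"][i]
                k = k * np.exp(-(drt**2) / (2.0 * sigma_rt**2))
            total += float(k.sum())
    return total
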