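"""MS1 feature tables: parsing, validation, top-N selection and normalization.

A mass-spectrometry run is represented as a bag of MS1 features, each a tuple
(m/z, intensity, charge, retention time in seconds) as produced by an upstream
feature finder.  Before any scoring, each run is reduced to its ``n`` most
intense features and its retention times and intensities are normalized
within-run:

* ``rt_norm``        — min-max scaling of retention time to [0, 1], so scores
  are invariant under any positive affine distortion of the chromatography
  time axis (gradient length, dead volume);
* ``intensity_norm`` — division by the run's maximum intensity, so scores are
  invariant under uniform intensity scaling (injection amount, detector gain).

Both normalizations are computed over the *post*-top-N feature set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRunError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Columns every feature table must provide, in canonical writer order.
REQUIRED_COLUMNS = ("mz", "intensity", "charge", "rt")


@dataclass(frozen=True, slots=True)
class MS1Feature:
    """One detected precursor.

    Parameters
    ----------
    mz : float
        Mass-to-charge ratio in Thomson; positive and finite.
    intensity : float
        Peak intensity in arbitrary units; non-negative.
    charge : int
        Precursor charge state; positive integer.
    rt : float
        Retention time in seconds; non-negative.
    rt_norm, intensity_norm : float
        Within-run normalized retention time / intensity in [0, 1];
        ``nan`` until :func:`normalize_run` has been applied.
    """

    mz: float
    intensity: float
    charge: int
    rt: float
    rt_norm: float = float("nan")
    intensity_norm: float = float("nan")

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mz) and self.mz > 0):
            raise ParameterError(f"mz must be finite and positive, got {self.mz}")
        if not (math.isfinite(self.intensity) and self.intensity >= 0):
            raise ParameterError(f"intensity must be finite and >= 0, got {self.intensity}")
        if int(self.charge) != self.charge or self.charge < 1:
            raise ParameterError(f"charge must be a positive integer, got {self.charge}")
        if not (math.isfinite(self.rt) and self.rt >= 0):
            raise ParameterError(f"rt must be finite and >= 0, got {self.rt}")

    def sort_key(self) -> tuple:
        """Canonical ordering key: descending intensity, then (mz, rt, charge)."""
        return (-self.intensity, self.mz, self.rt, self.charge)


@dataclass(slots=True)
class Run:
    """A run identifier plus the ordered bag of its MS1 features."""

    run_id: str
    features: list[MS1Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def is_normalized(self) -> bool:
        return bool(self.features) and all(
            math.isfinite(f.rt_norm) and math.isfinite(f.intensity_norm)
            for f in self.features
        )


def read_feature_table(path: str | Path, run_id: str | None = None) -> Run:
    """Read a tab-separated feature table into a :class:`Run`.

    The table must carry a header with at least the columns
    ``mz``, ``intensity``, ``charge`` and ``rt`` (retention time in seconds);
    an optional ``run_id`` column is ignored.  Rows with non-finite or
    non-positive m/z, negative intensity, charge < 1, non-integral charge, or
    negative retention time are dropped with a logged warning count.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        If a required column is missing.
    EmptyRunError
        If no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    n_raw = len(df)
    num = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    ok = (
        np.isfinite(num["mz"]) & (num["mz"] > 0)
        & np.isfinite(num["intensity"]) & (num["intensity"] >= 0)
        & np.isfinite(num["charge"]) & (num["charge"] >= 1)
        & (num["charge"] == np.floor(num["charge"]))
        & np.isfinite(num["rt"]) & (num["rt"] >= 0)
    )
    n_bad = int(n_raw - ok.sum())
    if n_bad:
        logger.warning("%s: dropped %d invalid feature row(s) of %d", path, n_bad, n_raw)
    num = num[ok]
    if num.empty:
        raise EmptyRunError(f"{path}: no valid feature rows")

    feats = [
        MS1Feature(mz=float(r.mz), intensity=float(r.intensity),
                   charge=int(r.charge), rt=float(r.rt))
        for r in num.itertuples(index=False)
    ]
    return Run(run_id=run_id or path.stem, features=feats)


def write_feature_table(run: Run, path: str | Path) -> None:
    """Write *run* in the canonical tab-separated dialect (raw values only)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for f in run.features:
            fh.write(f"{f.mz!r}\t{f.intensity!r}\t{f.charge}\t{f.rt!r}\n")


def select_top_n(run: Run, n: int) -> Run:
    """Keep the *n* most intense features of *run*, in canonical order.

    Intensity ties are broken by ascending (mz, rt, charge), making the
    selection deterministic and independent of input row order.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not run.features:
        raise EmptyRunError(f"run {run.run_id!r} is empty")
    ordered = sorted(run.features, key=MS1Feature.sort_key)
    return Run(run_id=run.run_id, features=ordered[:n])


def normalize_run(run: Run) -> Run:
    """Set ``rt_norm`` (min-max) and ``intensity_norm`` (max-scaling).

    Applied after top-N selection; idempotent because both statistics are
    recomputed from the raw values.  A single-feature run (or any run with a
    degenerate RT range) gets ``rt_norm = 0`` for all features; an all-zero
    intensity run gets ``intensity_norm = 0``.
    """
    if not run.features:
        raise EmptyRunError(f"run {run.run_id!r} is empty")
    rts = [f.rt for f in run.features]
    ints = [f.intensity for f in run.features]
    rt_min, rt_max = min(rts), max(rts)
    rt_range = rt_max - rt_min
    i_max = max(ints)
    out = [
        replace(
            f,
            rt_norm=(f.rt - rt_min) / rt_range if rt_range > 0 else 0.0,
            intensity_norm=f.intensity / i_max if i_max > 0 else 0.0,
        )
        for f in run.features
    ]
    return Run(run_id=run.run_id, features=out)


def prepare_run(run: Run, n: int) -> Run:
    """Top-N selection followed by normalization — the standard preprocessing."""
    return normalize_run(select_top_n(run, n))


def feature_arrays(run: Run) -> dict[str, np.ndarray]:
    """Columnar view of a run's features (mz, intensity, charge, rt, norms)."""
    return {
        "mz": np.array([f.mz for f in run.features], dtype=np.float64),
        "intensity": np.array([f.intensity for f in run.features], dtype=np.float64),
        "charge": np.array([f.charge for f in run.features], dtype=np.int64),
        "rt": np.array([f.rt for f in run.features], dtype=np.float64),
        "rt_norm": np.array([f.rt_norm for f in run.features], dtype=np.float64),
        "intensity_norm": np.array([f.intensity_norm for f in run.features], dtype=np.float64),
    }


def read_runs(paths: Iterable[str | Path]) -> list[Run]:
    """Read several feature tables, preserving the given order."""
    return [read_feature_table(p) for p in paths]
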