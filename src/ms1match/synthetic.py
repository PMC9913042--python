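"""Synthetic multi-species LC-MS feature-table generator.

Emulates a labeled repository of runs for end-to-end testing without any
external downloads.  Each species owns a pool of analytes (m/z in 300–1500 Th,
charge 2–3, a canonical elution position in [0, 1], a log-uniform base
intensity); a run from a species observes each pool analyte with a detection
probability and perturbs it with

* ppm-scale multiplicative m/z noise (mass accuracy),
* a per-run *affine* retention-time warp plus jitter (chromatography drift —
  exactly the distortion the within-run min-max RT normalization absorbs),
* log-normal intensity noise (injection/ionization variability),

and adds contaminant features drawn from a global pool shared by all species
(chemical background common to every experiment).  Pool m/z values are
rejection-sampled so that within-pool ppm separations exceed three times the
default edge tolerance, keeping identity matchings unambiguous in easy
settings.

Everything is reproducible from a single master seed; per-run seeds and warp
parameters are derived from it and recorded in a provenance file.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .features import MS1Feature, Run, write_feature_table
from .objective import ObjectiveParams

#: Minimum within-pool m/z separation, as a multiple of the default edge tolerance.
_SEPARATION_FACTOR = 3.0

#: Seconds per unit of canonical retention time (a one-hour gradient).
_RT_SCALE_S = 3600.0


class Analyte(NamedTuple):
    mz: float
    charge: int
    canonical_rt: float
    base_intensity: float


@dataclass(slots=True)
class SpeciesLibrary:
    """Per-species analyte pools plus a global contaminant pool."""

    species: dict[str, list[Analyte]]
    contaminants: list[Analyte]
    shared_fraction: float
    seed: int


@dataclass(frozen=True, slots=True)
class SimParams:
    """Observation-noise model for one simulated run.

    ``rt_warp = (slope, intercept, jitter_sigma)`` acts on canonical RT in
    [0, 1] before conversion to seconds; the defaults are the benchmark
    acquisition conditions (80% detection, 1 ppm mass noise, 1% RT jitter,
    25 background features).
    """

    detection_prob: float = 0.8
    ppm_sigma: float = 1.0
    rt_warp: tuple[float, float, float] = (1.0, 0.0, 0.01)
    intensity_sigma_log: float = 0.3
    n_contaminants: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.detection_prob <= 1):
            raise ParameterError(f"detection_prob must be in (0, 1], got {self.detection_prob}")
        if self.ppm_sigma < 0 or self.intensity_sigma_log < 0:
            raise ParameterError("noise sigmas must be >= 0")
        slope, _, jitter = self.rt_warp
        if slope <= 0:
            raise ParameterError(f"rt warp slope must be positive, got {slope}")
        if jitter < 0:
            raise ParameterError(f"rt jitter must be >= 0, got {jitter}")
        if self.n_contaminants < 0:
            raise ParameterError("n_contaminants must be >= 0")

    def header_lines(self) -> list[str]:
        return [
            f"detection_prob={self.detection_prob}",
            f"ppm_sigma={self.ppm_sigma}",
            f"rt_warp={self.rt_warp}",
            f"intensity_sigma_log={self.intensity_sigma_log}",
            f"n_contaminants={self.n_contaminants}",
            f"seed={self.seed}",
        ]


def _draw_pool(
    rng: np.random.Generator,
    size: int,
    min_sep_ppm: float,
    existing: list[Analyte] | None = None,
) -> list[Analyte]:
    """Rejection-sample a pool with pairwise m/z separations > *min_sep_ppm*."""
    # density guard: analytes occupy ~min_sep ppm slots on a log-m/z axis,
    # giving a capacity of ln(1500/300)/(min_sep*1e-6); beyond half of it the
    # rejection loop degenerates
    capacity = float(np.log(1500.0 / 300.0) / (min_sep_ppm * 1e-6))
    if size > 0.5 * capacity:
        raise ParameterError(
            f"pool too dense: {size} analytes with {min_sep_ppm} ppm separation "
            f"exceeds half the 300-1500 Th capacity (~{int(capacity)})"
        )
    mzs: list[float] = [a.mz for a in existing] if existing else []
    pool: list[Analyte] = list(existing) if existing else []
    attempts = 0
    limit = 1000 * (size + 1)
    while len(pool) < size:
        attempts += 1
        if attempts > limit:
            raise ParameterError(
                f"pool too dense: cannot place {size} analytes with "
                f"{min_sep_ppm} ppm separation in 300-1500 Th"
            )
        mz = float(rng.uniform(300.0, 1500.0))
        if any(abs(mz - m) / ((mz + m) / 2.0) * 1e6 <= min_sep_ppm for m in mzs):
            continue
        pool.append(Analyte(
            mz=mz,
            charge=int(rng.integers(2, 4)),
            canonical_rt=float(rng.uniform(0.0, 1.0)),
            base_intensity=float(np.exp(rng.uniform(np.log(1e5), np.log(1e8)))),
        ))
        mzs.append(mz)
    return pool


def make_library(
    n_species: int,
    pool_size: int,
    shared_fraction: float,
    seed: int,
    n_contaminant_pool: int = 200,
    delta1_ppm: float | None = None,
) -> SpeciesLibrary:
    """Build species analyte pools plus the shared contaminant pool.

    With ``shared_fraction > 0``, consecutive species pairs (0,1), (2,3), …
    share that fraction of their pools as identical analyte tuples.  Pools
    are rejection-sampled so within-pool separations exceed three times the
    edge tolerance (default: the standard 4 ppm).
    """
    if n_species < 1 or pool_size < 1:
        raise ParameterError("n_species and pool_size must be >= 1")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ParameterError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    tol = delta1_ppm if delta1_ppm is not None else ObjectiveParams().delta1_ppm
    min_sep = _SEPARATION_FACTOR * tol
    rng = np.random.default_rng(seed)

    n_shared = int(round(shared_fraction * pool_size))
    species: dict[str, list[Analyte]] = {}
    for i in range(n_species):
        label = f"species_{i}"
        if n_shared and i % 2 == 1:
            partner = species[f"species_{i - 1}"]
            shared = partner[:n_shared]
            species[label] = _draw_pool(rng, pool_size, min_sep, existing=shared)
        else:
            species[label] = _draw_pool(rng, pool_size, min_sep)
    contaminants = _draw_pool(rng, n_contaminant_pool, min_sep)
    return SpeciesLibrary(species=species, contaminants=contaminants,
                          shared_fraction=shared_fraction, seed=seed)


def simulate_run(
    lib: SpeciesLibrary,
    label: str,
    p: SimParams,
    run_id: str | None = None,
    out_path: str | Path | None = None,
) -> Run:
    """Observe one run of *label*'s pool under the noise model *p*.

    Deterministic for a fixed ``p.seed``; optionally writes the feature
    table in the standard TSV dialect.
    """
    if label not in lib.species:
        raise ParameterError(f"unknown species label {label!r}")
    rng = np.random.default_rng(p.seed)
    slope, intercept, jitter = p.rt_warp

    feats: list[MS1Feature] = []

    def observe(a: Analyte) -> MS1Feature:
        eps = rng.normal(0.0, p.ppm_sigma) if p.ppm_sigma > 0 else 0.0
        mz = a.mz * (1.0 + eps / 1e6)
        t = slope * a.canonical_rt + intercept
        if jitter > 0:
            t += rng.normal(0.0, jitter)
        rt = max(t, 0.0) * _RT_SCALE_S
        inten = a.base_intensity
        if p.intensity_sigma_log > 0:
            inten *= float(np.exp(rng.normal(0.0, p.intensity_sigma_log)))
        return MS1Feature(mz=mz, intensity=inten, charge=a.charge, rt=rt)

    for a in lib.species[label]:
        if rng.uniform() <= p.detection_prob:
            feats.append(observe(a))
    if p.n_contaminants:
        n = min(p.n_contaminants, len(lib.contaminants))
        picks = rng.choice(len(lib.contaminants), size=n, replace=False)
        for k in picks:
            feats.append(observe(lib.contaminants[int(k)]))

    run = Run(run_id=run_id or f"{label}_run{p.seed}", features=feats)
    if out_path is not None:
        write_feature_table(run, out_path)
    return run


@dataclass(slots=True)
class SyntheticDataset:
    runs: list[Run]
    labels: dict[str, str]
    library: SpeciesLibrary
    out_dir: Path | None = None


def simulate_dataset(
    n_species: int,
    runs_per_species: int,
    p: SimParams,
    out_dir: str | Path | None = None,
    pool_size: int = 500,
    shared_fraction: float = 0.0,
    slope_range: tuple[float, float] = (0.8, 1.2),
    intercept_range: tuple[float, float] = (0.0, 0.2),
) -> SyntheticDataset:
    """Simulate a labeled repository of ``n_species × runs_per_species`` runs.

    Per-run seeds and affine RT warps (slope, intercept drawn uniformly from
    the given ranges) are derived from the master seed ``p.seed``, emulating
    independent chromatography conditions across experiments.  When *out_dir*
    is given, writes one feature table per run, a ``labels.tsv`` and a
    ``provenance.txt`` recording all parameters.
    """
    master = np.random.default_rng(p.seed)
    lib = make_library(n_species, pool_size, shared_fraction,
                       seed=int(master.integers(0, 2**31 - 1)))
    runs: list[Run] = []
    labels: dict[str, str] = {}
    for label in lib.species:
        for j in range(runs_per_species):
            warp = (
                float(master.uniform(*slope_range)),
                float(master.uniform(*intercept_range)),
                p.rt_warp[2],
            )
            run_p = replace(p, rt_warp=warp, seed=int(master.integers(0, 2**31 - 1)))
            run_id = f"{label}_r{j}"
            run = simulate_run(lib, label, run_p, run_id=run_id)
            runs.append(run)
            labels[run_id] = label

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for run in runs:
            write_feature_table(run, out_dir / f"{run.run_id}.tsv")
        with (out_dir / "labels.tsv").open("w", encoding="utf-8") as fh:
            for rid, lab in labels.items():
                fh.write(f"{rid}\t{lab}\n")
        with (out_dir / "provenance.txt").open("w", encoding="utf-8") as fh:
            fh.write(f"n_species={n_species}\nruns_per_species={runs_per_species}\n")
            fh.write(f"pool_size={pool_size}\nshared_fraction={shared_fraction}\n")
            fh.write(f"slope_range={slope_range}\nintercept_range={intercept_range}\n")
            for line in p.header_lines():
                fh.write(line + "\n")
    return SyntheticDataset(runs=runs, labels=labels, library=lib,
                            out_dir=Path(out_dir) if out_dir is not None else None)
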