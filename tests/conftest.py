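"""Shared builders for hand-crafted runs and small random bipartite graphs."""

from __future__ import annotations

import numpy as np
import pytest

from ms1match import (
    MS1Feature,
    ObjectiveParams,
    Run,
    build_edges,
    prepare_run,
)


def make_run(rows, run_id="run", normalized=True):
    """Run from (mz, intensity, charge, rt) tuples; canonical prep applied."""
    feats = [MS1Feature(mz=m, intensity=i, charge=z, rt=t) for m, i, z, t in rows]
    run = Run(run_id=run_id, features=feats)
    if normalized:
        run = prepare_run(run, n=len(feats))
    return run


def random_lambdas(rng, modular=False):
    """Uniform draw on the λ simplex (λ4 forced to 0 when *modular*)."""
    k = 3 if modular else 4
    lam = rng.uniform(size=k)
    lam = lam / lam.sum()
    out = list(lam) + ([0.0] if modular else [])
    out[2] = max(1.0 - (out[0] + out[1] + out[3]), 0.0)  # exact simplex closure
    return tuple(out)


def random_params(rng, modular=False):
    l1, l2, l3, l4 = random_lambdas(rng, modular=modular)
    return ObjectiveParams(
        n_features=1000,
        delta1_ppm=4.0,
        lambda1=l1, lambda2=l2, lambda3=l3, lambda4=l4,
        alpha=float(rng.uniform(0.1, 5.0)),
        beta=float(rng.uniform(0.1, 20.0)),
        gamma=float(rng.uniform(0.1, 20.0)),
    )


def random_small_graph(rng, n_clusters=3, max_per_side=2, delta1=4.0):
    """A random graph with |E| ≤ n_clusters * max_per_side².

    Features are grouped in well-separated m/z clusters; within a cluster all
    cross-run pairs fall inside the ppm tolerance, so the edge count is the
    sum of per-cluster side products.
    """
    centers = np.array([400.0, 650.0, 900.0, 1150.0, 1400.0])[:n_clusters]
    rows_u, rows_v = [], []
    for c in centers:
        z = int(rng.integers(2, 4))
        for _ in range(int(rng.integers(0, max_per_side + 1))):
            mz = c * (1.0 + rng.uniform(-1.0, 1.0) * 1e-6)  # within ±1 ppm
            rows_u.append((mz, float(rng.uniform(1e5, 1e7)), z, float(rng.uniform(0, 3600))))
        for _ in range(int(rng.integers(0, max_per_side + 1))):
            mz = c * (1.0 + rng.uniform(-1.0, 1.0) * 1e-6)
            rows_v.append((mz, float(rng.uniform(1e5, 1e7)), z, float(rng.uniform(0, 3600))))
    # guarantee nonempty runs so normalization is defined
    rows_u.append((50.0, 1.0, 1, 0.0))
    rows_v.append((60.0, 1.0, 1, 0.0))
    run_u = make_run(rows_u, run_id="u")
    run_v = make_run(rows_v, run_id="v")
    return build_edges(run_u, run_v, delta1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def adversarial_graph():
    """Three-edge instance where greedy (under the intensity term) is 0.6-suboptimal.

    U has features u1 (norm intensity 1.0) and u2 (0.8); V has v1 (0.2),
    v2 (0.0) and a filler v3 that anchors V's intensity maximum.  Edges:
    (u1,v1) weight 0.6, (u2,v1) 0.5, (u1,v2) 0.5.  Greedy takes (u1,v1) and
    blocks both alternatives; the optimum pairs (u2,v1) with (u1,v2).
    """
    run_u = make_run(
        [(500.0000, 1.0, 2, 0.0), (500.0010, 0.8, 2, 0.0)], run_id="adv_u"
    )
    run_v = make_run(
        [(500.0005, 0.2, 2, 0.0), (499.9995, 0.0, 2, 0.0), (900.0, 1.0, 2, 0.0)],
        run_id="adv_v",
    )
    g = build_edges(run_u, run_v, delta1_ppm=2.0)
    p = ObjectiveParams(lambda1=0.0, lambda2=1.0, lambda3=0.0, lambda4=0.0)
    return g, p
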