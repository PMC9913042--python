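"""Objective entries, term totals, normalizers and the supermodularity of M4."""

import itertools

import numpy as np
import pytest

from ms1match import ObjectiveParams, ParameterError, build_edges, diag_entry, pair_entry, term_totals
from ms1match.objective import m4_total, normalized_value

from conftest import make_run, random_params, random_small_graph


def _m4_bruteforce(g, p, idx):
    """Independent O(k^2) double loop over Edge objects via pair_entry."""
    edges = [g.edges[k] for k in idx]
    return sum(pair_entry(e1, e2, p) for e1 in edges for e2 in edges)


@pytest.fixture
def two_shift_graph():
    """Two edges with distinct shifts/positions plus known intensities."""
    u = make_run([(500.000, 2e5, 2, 0.0), (700.000, 1e5, 2, 100.0)], run_id="u")
    v = make_run(
        [(500.001, 1e5, 2, 30.0), (700.001, 2e5, 2, 60.0), (900.0, 5e4, 3, 100.0)],
        run_id="v",
    )
    return build_edges(u, v, 4.0)


class TestDiagEntry:
    def test_m1_always_one(self, two_shift_graph):
        p = ObjectiveParams()
        for e in two_shift_graph.edges:
            assert diag_entry(e, two_shift_graph, p)[0] == 1.0

    def test_m2_is_mean_normalized_intensity(self, two_shift_graph):
        p = ObjectiveParams()
        m2s = sorted(diag_entry(e, two_shift_graph, p)[1] for e in two_shift_graph.edges)
        assert m2s == [pytest.approx(0.75), pytest.approx(0.75)]

    def test_m3_exponential_decay_zero_shift(self):
        u = make_run([(500.000, 1.0, 2, 0.0), (900.0, 1.0, 2, 100.0)])
        v = make_run([(500.001, 1.0, 2, 0.0), (900.0, 1.0, 2, 100.0)])
        g = build_edges(u, v, 4.0)
        p = ObjectiveParams(alpha=1.0)
        for e in g.edges:
            assert e.rt_shift == 0.0
            assert diag_entry(e, g, p)[2] == 1.0

    def test_m3_known_shift(self):
        # paired features elute at rt_norm 0.0 (u) vs 0.2 (v): anchors at both
        # RT extremes pin each run's min-max scale
        u = make_run([(500.000, 1.0, 2, 0.0), (900.0, 1.0, 2, 100.0)])
        v = make_run([(500.001, 1.0, 2, 20.0), (900.0, 1.0, 2, 100.0),
                      (300.0, 1.0, 2, 0.0)])
        g = build_edges(u, v, 4.0)
        p = ObjectiveParams(alpha=1.0)
        e = next(e for e in g.edges if e.ppm_delta > 1.0)
        assert abs(e.rt_shift) == pytest.approx(0.2)
        assert diag_entry(e, g, p)[2] == pytest.approx(np.exp(-0.2))

    def test_entries_in_unit_interval(self, rng):
        for _ in range(10):
            g = random_small_graph(rng)
            p = random_params(rng)
            for e in g.edges:
                m1, m2, m3 = diag_entry(e, g, p)
                assert 0.0 <= m2 <= 1.0 and 0.0 <= m3 <= 1.0 and m1 == 1.0


class TestPairEntry:
    def test_identity_is_one(self, two_shift_graph):
        p = ObjectiveParams(beta=10.0, gamma=10.0)
        for e in two_shift_graph.edges:
            assert pair_entry(e, e, p) == 1.0

    def test_no_decay_when_beta_gamma_zero(self, two_shift_graph):
        p = ObjectiveParams(beta=0.0, gamma=0.0)
        e1, e2 = two_shift_graph.edges
        assert pair_entry(e1, e2, p) == 1.0

    def test_symmetric(self, rng):
        for _ in range(10):
            g = random_small_graph(rng)
            if g.n_edges < 2:
                continue
            p = random_params(rng)
            for e1, e2 in itertools.combinations(g.edges, 2):
                assert pair_entry(e1, e2, p) == pair_entry(e2, e1, p)

    def test_matches_closed_form(self, two_shift_graph):
        p = ObjectiveParams(beta=2.0, gamma=3.0)
        e1, e2 = two_shift_graph.edges
        d_shift = abs(e1.rt_shift - e2.rt_shift)
        d_pos = (abs(e1.rt_u - e2.rt_u) + abs(e1.rt_v - e2.rt_v)) / 2
        assert pair_entry(e1, e2, p) == pytest.approx(np.exp(-(2.0 * d_shift + 3.0 * d_pos)))

    def test_swap_invariant(self, rng):
        """m4 between corresponding edges is unchanged when runs are swapped."""
        for _ in range(10):
            g = random_small_graph(rng)
            if g.n_edges < 2:
                continue
            h = build_edges(g.run_v, g.run_u, g.delta1_ppm)
            p = random_params(rng)
            for k1, k2 in itertools.combinations(range(g.n_edges), 2):
                assert pair_entry(g.edges[k1], g.edges[k2], p) == pair_entry(
                    h.edges[k1], h.edges[k2], p
                )


class TestTermTotals:
    def test_empty_set(self, two_shift_graph):
        tb = term_totals([], two_shift_graph, ObjectiveParams())
        assert tb.totals == (0.0, 0.0, 0.0, 0.0)

    def test_single_edge_m4_is_diagonal_one(self, two_shift_graph):
        tb = term_totals([0], two_shift_graph, ObjectiveParams())
        assert tb.m1 == 1.0
        assert tb.m4 == pytest.approx(1.0)

    def test_two_edges_beta_gamma_zero_gives_m4_four(self, two_shift_graph):
        p = ObjectiveParams(beta=0.0, gamma=0.0)
        tb = term_totals([0, 1], two_shift_graph, p)
        assert tb.m4 == pytest.approx(4.0)

    def test_m4_matches_pairwise_bruteforce(self, rng):
        for _ in range(20):
            g = random_small_graph(rng)
            if g.n_edges == 0:
                continue
            p = random_params(rng)
            k = int(rng.integers(1, g.n_edges + 1))
            idx = rng.choice(g.n_edges, size=k, replace=False)
            tb = term_totals(idx, g, p)
            assert tb.m4 == pytest.approx(_m4_bruteforce(g, p, idx), rel=1e-9)

    def test_normalizers_bound_subset_totals(self, rng):
        for _ in range(20):
            g = random_small_graph(rng)
            if g.n_edges == 0:
                continue
            p = random_params(rng)
            k = int(rng.integers(1, g.n_edges + 1))
            idx = rng.choice(g.n_edges, size=k, replace=False)
            tb = term_totals(idx, g, p)
            for total, norm in zip(tb.totals, tb.normalizers):
                assert total <= norm + 1e-9

    def test_m4_bounds(self, rng):
        """|A| <= M4(A) <= |A|^2 for every subset."""
        for _ in range(20):
            g = random_small_graph(rng)
            if g.n_edges == 0:
                continue
            p = random_params(rng)
            k = int(rng.integers(1, g.n_edges + 1))
            idx = rng.choice(g.n_edges, size=k, replace=False)
            tb = term_totals(idx, g, p)
            assert k - 1e-9 <= tb.m4 <= k * k + 1e-9

    def test_accepts_edge_objects(self, two_shift_graph):
        p = ObjectiveParams()
        by_idx = term_totals([0, 1], two_shift_graph, p)
        by_edge = term_totals(list(two_shift_graph.edges), two_shift_graph, p)
        assert by_idx.totals == by_edge.totals


class TestM4Supermodularity:
    def test_marginal_gains_grow_with_context(self, rng):
        """For A ⊆ B and e ∉ B: M4(B+e) − M4(B) ≥ M4(A+e) − M4(A)."""
        checked = 0
        while checked < 60:
            g = random_small_graph(rng, n_clusters=2)
            if g.n_edges < 3 or g.n_edges > 10:
                continue
            p = random_params(rng)
            all_idx = list(range(g.n_edges))
            e = int(rng.choice(all_idx))
            rest = [k for k in all_idx if k != e]
            nb = int(rng.integers(1, len(rest) + 1))
            b = list(rng.choice(rest, size=nb, replace=False))
            na = int(rng.integers(0, nb + 1))
            a = list(rng.choice(b, size=na, replace=False)) if na else []

            def m4(idx):
                return term_totals(idx, g, p).m4 if idx else 0.0

            gain_b = m4(b + [e]) - m4(b)
            gain_a = m4(a + [e]) - m4(a)
            assert gain_b >= gain_a - 1e-9
            checked += 1

    def test_modular_terms_are_additive(self, rng):
        """M1..M3 of a disjoint union is the sum of the parts."""
        for _ in range(10):
            g = random_small_graph(rng)
            if g.n_edges < 2:
                continue
            p = random_params(rng)
            idx = list(rng.permutation(g.n_edges))
            cut = len(idx) // 2
            x, y = idx[:cut], idx[cut:]
            tx, ty, txy = term_totals(x, g, p), term_totals(y, g, p), term_totals(idx, g, p)
            for i in range(3):
                assert txy.totals[i] == pytest.approx(tx.totals[i] + ty.totals[i], rel=1e-12)


class TestObjectiveParams:
    def test_lambda_sum_enforced(self):
        with pytest.raises(ParameterError, match="sum to 1"):
            ObjectiveParams(lambda1=0.3, lambda2=0.3, lambda3=0.3, lambda4=0.3)

    def test_lambda_range_enforced(self):
        with pytest.raises(ParameterError):
            ObjectiveParams(lambda1=-0.1, lambda2=0.5, lambda3=0.3, lambda4=0.3)

    def test_defaults_are_best_search_configuration(self):
        p = ObjectiveParams()
        assert p.n_features == 4000
        assert p.delta1_ppm == 4.0
        assert p.lambda4 == 0.9

    def test_without_supermodular_redistributes(self):
        p = ObjectiveParams().without_supermodular()
        assert p.lambda4 == 0.0
        assert sum(p.lambdas) == pytest.approx(1.0)
        assert p.lambda3 == pytest.approx(0.5)

    def test_single_term(self):
        p = ObjectiveParams().single_term(4)
        assert p.lambdas == (0.0, 0.0, 0.0, 1.0)

    def test_normalized_value_degenerate_zero(self, two_shift_graph):
        tb = term_totals([], two_shift_graph, ObjectiveParams())
        assert normalized_value(tb, ObjectiveParams()) >= 0.0
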