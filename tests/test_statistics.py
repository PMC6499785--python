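"""ERGM configuration statistics and change statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from senet.statistics import (ERGMSpec, Statistic, change_statistic,
                              encode_model, global_statistics,
                              se_closure_count, statistics_from_adjacency)

from conftest import make_actors, make_network, random_graph, random_multilevel

FULL_SPEC = ERGMSpec.from_names(
    "edge_density,two_star,alt_star,alt_triangle,leader_activity,"
    "site_homophily,site_activity:a,se_closure")


def brute_alt_star(A, lam):
    """Alternating sum over brute-force k-star counts."""
    n = A.shape[0]
    total = 0.0
    for k in range(2, n):
        s_k = 0
        for c in range(n):
            neigh = [j for j in range(n) if A[c, j]]
            s_k += sum(1 for _ in itertools.combinations(neigh, k))
        total += (-1) ** k * s_k / lam ** (k - 2)
    return total


def brute_alt_triangle(A, lam):
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j]:
                p = sum(1 for t in range(n) if A[i, t] and A[j, t])
                total += lam * (1 - (1 - 1 / lam) ** p)
    return total


def brute_se_closure(A, X):
    n, m = X.shape
    return sum(1 for i in range(n) for j in range(i + 1, n) for u in range(m)
               if A[i, j] and X[i, u] and X[j, u])


class TestGlobalStatistics:
    def test_star_k13_alternating_star(self):
        A = np.zeros((4, 4), dtype=np.int8)
        A[0, 1:] = A[1:, 0] = 1
        spec = ERGMSpec.from_names("alt_star,two_star")
        z = global_statistics(make_network(A), None, spec)
        assert z[0] == pytest.approx(2.5)  # S2 - S3/2 = 3 - 0.5
        assert z[1] == 3

    def test_triangle_alternating_triangle(self):
        A = 1 - np.eye(3, dtype=np.int8)
        z = global_statistics(make_network(A), None,
                              ERGMSpec.from_names("alt_triangle"))
        assert z[0] == pytest.approx(3.0)

    def test_single_edge_star_terms_vanish(self):
        A = np.zeros((4, 4), dtype=np.int8)
        A[0, 1] = A[1, 0] = 1
        z = global_statistics(make_network(A), None,
                              ERGMSpec.from_names("alt_star,two_star"))
        assert (z == 0).all()

    def test_empty_network_all_statistics_zero(self, rng):
        net = random_multilevel(rng, n=8, m=4)
        net.A[:] = 0
        actors = make_actors(8, rng)
        z = global_statistics(net, actors, FULL_SPEC)
        assert (z == 0).all()

    def test_lambda_must_exceed_one(self):
        with pytest.raises(ValueError, match="lambda"):
            Statistic("alt_star", lam=1.0)

    def test_attribute_statistics_direct_sums(self, rng):
        net = random_multilevel(rng, n=10)
        actors = make_actors(10, rng)
        spec = ERGMSpec.from_names("leader_activity,site_homophily")
        z = global_statistics(net, actors, spec)
        L = actors["leader"].to_numpy()
        s = actors["landing_site"].to_numpy()
        exp_leader = sum(net.A[i, j] * (L[i] + L[j])
                         for i in range(10) for j in range(i + 1, 10))
        exp_hom = sum(net.A[i, j] * (s[i] == s[j])
                      for i in range(10) for j in range(i + 1, 10))
        assert z[0] == exp_leader and z[1] == exp_hom


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(6))
    def test_alternating_statistics_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        A = random_graph(rng, n, 0.4)
        net = make_network(A)
        for lam in (1.5, 2.0, 3.0):
            spec = ERGMSpec([Statistic("alt_star", lam=lam),
                             Statistic("alt_triangle", lam=lam)])
            z = global_statistics(net, None, spec)
            assert z[0] == pytest.approx(brute_alt_star(A, lam), abs=1e-9)
            assert z[1] == pytest.approx(brute_alt_triangle(A, lam), abs=1e-9)


class TestSeClosure:
    def test_one_shared_species(self):
        A = np.zeros((2, 2), dtype=np.int8)
        A[0, 1] = A[1, 0] = 1
        X = np.array([[1, 1, 0], [0, 1, 1]], dtype=np.int8)
        assert se_closure_count(make_network(A, X)) == 1

    def test_empty_social_network_zero(self, rng):
        net = random_multilevel(rng, n=6, m=4)
        net.A[:] = 0
        assert se_closure_count(net) == 0

    def test_matches_triple_enumeration(self, rng):
        net = random_multilevel(rng, n=10, m=6)
        assert se_closure_count(net) == brute_se_closure(net.A, net.X)

    def test_invariant_under_species_relabeling(self, rng):
        net = random_multilevel(rng, n=8, m=6)
        perm = rng.permutation(6)
        net2 = make_network(net.A, net.X[:, perm])
        assert se_closure_count(net2) == se_closure_count(net)


class TestChangeStatistics:
    def test_disjoint_x_rows_zero_closure_change(self):
        A = np.zeros((2, 2), dtype=np.int8)
        X = np.array([[1, 0], [0, 1]], dtype=np.int8)
        d = change_statistic(make_network(A, X), None,
                             ERGMSpec.from_names("se_closure"), (0, 1))
        assert d[0] == 0

    def test_leader_change_is_flag_sum(self, rng):
        net = random_multilevel(rng, n=4)
        actors = make_actors(4, rng)
        actors["leader"] = [True, False, False, True]
        spec = ERGMSpec.from_names("leader_activity")
        assert change_statistic(net, actors, spec, (0, 1))[0] == 1
        assert change_statistic(net, actors, spec, (0, 3))[0] == 2
        assert change_statistic(net, actors, spec, (1, 2))[0] == 0

    def test_accepts_actor_ids(self, rng):
        net = random_multilevel(rng, n=5)
        spec = ERGMSpec.from_names("edge_density")
        assert change_statistic(net, None, spec, ("f0", "f1"))[0] == 1
        with pytest.raises(KeyError):
            change_statistic(net, None, spec, ("f0", "nobody"))

    def test_matches_global_difference_on_random_toggles(self):
        """500 random toggles: local change equals full recount difference."""
        rng = np.random.default_rng(7)
        net = random_multilevel(rng, n=20, m=6, p_a=0.2)
        actors = make_actors(20, rng)
        enc = encode_model(net, actors, FULL_SPEC)
        for _ in range(500):
            i, j = rng.integers(0, 20, 2)
            if i == j:
                continue
            off = net.A.copy()
            off[i, j] = off[j, i] = 0
            on = off.copy()
            on[i, j] = on[j, i] = 1
            diff = (statistics_from_adjacency(on, enc)
                    - statistics_from_adjacency(off, enc))
            d = change_statistic(net, actors, FULL_SPEC, (int(i), int(j)))
            assert np.array_equal(d, diff)

    @given(st.integers(0, 10_000))
    def test_change_matches_global_difference_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        net = random_multilevel(rng, n=n, m=4, p_a=0.4)
        actors = make_actors(n, rng)
        spec = ERGMSpec.from_names(
            "edge_density,two_star,alt_star,alt_triangle,se_closure")
        enc = encode_model(net, actors, spec)
        i, j = 0, n - 1
        off = net.A.copy()
        off[i, j] = off[j, i] = 0
        on = off.copy()
        on[i, j] = on[j, i] = 1
        diff = (statistics_from_adjacency(on, enc)
                - statistics_from_adjacency(off, enc))
        d = change_statistic(net, actors, spec, (i, j))
        assert np.allclose(d, diff, atol=1e-9)


class TestSpec:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ERGMSpec.from_names("edge_density,edge_density")

    def test_parse_tokens(self):
        spec = ERGMSpec.from_names("edge_density,alt_star:3.0,site_activity:pier")
        assert spec.names == ["edge_density", "alt_star(3)",
                              "site_activity(pier)"]

    def test_site_activity_unknown_site_rejected(self, rng):
        net = random_multilevel(rng, n=4)
        actors = make_actors(4, rng)
        spec = ERGMSpec.from_names("site_activity:nowhere")
        with pytest.raises(ValueError, match="unknown landing site"):
            encode_model(net, actors, spec)
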