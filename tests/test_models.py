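"""Edge-probability builders and the two compound-edit showcase processes."""

import math

import numpy as np
import pytest

from editchains import (
    edge_probability_model,
    family_spectrum,
    fixture_host,
    intersection_family,
    moran_family,
    moran_recurrent_states,
    moran_spectrum_and_bounds,
    simulate,
    simulate_sampler,
    stationary_numeric,
    stationary_simple,
    transition_matrix,
)
from editchains.chain import recurrent_classes
from editchains.host import subgraph_is_forest


class TestEdgeProbabilityModels:
    def test_er_uniform(self):
        host, p = edge_probability_model("er", n=3, p=0.5)
        assert host.m == 3 and np.allclose(p, 0.5)

    def test_chung_lu_formula(self):
        host, p = edge_probability_model("chung_lu", degrees=(1, 1, 2))
        assert p[host.edge_index("1", "3")] == pytest.approx(2 / 4)

    def test_chung_lu_degree_condition(self):
        with pytest.raises(ValueError, match="max_v k_v"):
            edge_probability_model("chung_lu", degrees=(1, 1, 9))

    def test_sbm_within_and_between(self):
        host, p = edge_probability_model(
            "sbm", parts=(["1", "2"], ["3", "4"]), p=0.7, q=0.1
        )
        assert p[host.edge_index("1", "2")] == pytest.approx(0.7)
        assert p[host.edge_index("1", "3")] == pytest.approx(0.1)

    def test_sbm_disjointness(self):
        with pytest.raises(ValueError, match="disjoint"):
            edge_probability_model("sbm", parts=(["1"], ["1", "2"]), p=0.5, q=0.5)

    @pytest.mark.parametrize(
        "model, params",
        [
            ("er", {"n": 4, "p": 0.3}),
            ("chung_lu", {"degrees": (1.0, 1.5, 2.0, 2.5)}),
            ("sbm", {"parts": (["1", "2"], ["3", "4"]), "p": 0.6, "q": 0.2}),
        ],
    )
    def test_stationary_law_is_edge_independent(self, model, params):
        """Eq-independent product law: correct marginals and pairwise
        independence of edges under the stationary distribution."""
        host, p = edge_probability_model(model, **params)
        pi = stationary_simple(host, p)
        states = np.arange(1 << host.m)
        for e in range(host.m):
            assert pi[(states >> e) & 1 == 1].sum() == pytest.approx(p[e])
        for e in range(host.m):
            for f in range(e + 1, host.m):
                both = ((states >> e) & 1 == 1) & ((states >> f) & 1 == 1)
                assert pi[both].sum() == pytest.approx(p[e] * p[f])


class TestMoranFamily:
    def test_k4_has_12_uniform_edits(self, k4):
        family, _ = moran_family(k4)
        assert len(family) == 12
        assert np.allclose(family.weights, 1 / 12)

    def test_applied_edit_leaves_endpoint_with_degree_one(self, k4):
        family, spec = moran_family(k4)
        rng = np.random.default_rng(0)
        for (u, v), edit in zip(spec.oriented_edges, family.edits):
            state = int(rng.integers(0, 1 << k4.m))
            after = edit.apply_bits(state)
            deg_u = bin(after & k4.neighborhood(u).bits).count("1")
            assert deg_u == 1

    def test_isolated_vertex_rejected(self):
        from editchains.host import HostGraph

        host = HostGraph(("1", "2", "3"), ((0, 1),))
        with pytest.raises(ValueError, match="isolated"):
            moran_family(host)


class TestMoranSpectrum:
    def test_k3_neighborhood_eigenvalue(self, k3):
        _, spec = moran_family(k3)
        assert spec.lambda_closed_form(k3.neighborhood("1")) == pytest.approx(1 / 3)

    def test_k4_pair_union_eigenvalue_is_second_largest(self, k4):
        _, spec = moran_family(k4)
        X = k4.neighborhood("1") | k4.neighborhood("2")
        assert spec.lambda_closed_form(X) == pytest.approx(0.5)
        assert spec.second_eigenvalue_bound == pytest.approx(0.5)

    def test_full_edge_set_eigenvalue_one(self, k4):
        _, spec = moran_family(k4)
        assert spec.lambda_closed_form(k4.full_subset) == pytest.approx(1.0)

    @pytest.mark.parametrize("fixture", ["kn:3", "k4"])
    def test_closed_form_matches_numeric_spectrum(self, fixture):
        host = fixture_host(fixture)
        family, spec = moran_family(host)
        spectrum, t = moran_spectrum_and_bounds(spec, c=1.0)
        T = transition_matrix(family)
        states = recurrent_classes(T)[0]
        numeric = np.sort(np.linalg.eigvals(T.P[np.ix_(states, states)]).real)[::-1]
        assert np.allclose(numeric, spectrum.eigenvalues_multiset(), atol=1e-9)
        assert spectrum.total_multiplicity == len(states)
        assert spectrum.lambda_star <= spec.second_eigenvalue_bound + 1e-12
        assert t == math.ceil(host.m * (host.m * math.log(2) + 1.0) / host.min_degree)

    def test_kn_sharpened_bound(self):
        _, spec = moran_family(fixture_host("k4"))
        assert spec.kn_mixing_time(4, 1.0) == math.ceil((16 * math.log(4) + 4) / 2)
        assert spec.forest_count_bound(4) == (4 - 1) ** 4


class TestMoranRecurrentStates:
    def test_k3_recurrent_equals_chambers(self, k3):
        from editchains import chambers, generate_semigroup

        family, _ = moran_family(k3)
        rec = {s.bits for s in moran_recurrent_states(k3)}
        _, mapping = chambers(generate_semigroup(list(family.edits)))
        assert rec == {s.bits for s in mapping.values()}

    @pytest.mark.parametrize("fixture", ["kn:3", "k4"])
    def test_recurrent_states_are_forests(self, fixture):
        host = fixture_host(fixture)
        for s in moran_recurrent_states(host):
            assert subgraph_is_forest(host, s)

    def test_k4_full_edge_set_is_transient(self, k4):
        rec = {s.bits for s in moran_recurrent_states(k4)}
        assert k4.full_subset.bits not in rec

    def test_long_run_frequencies_match_stationary(self, k4):
        family, _ = moran_family(k4)
        T = transition_matrix(family)
        pi = stationary_numeric(T)
        steps, burn = 10**5, 10**3
        traj = simulate(family, k4.full_subset, steps, seed=11)
        emp = traj.empirical_distribution(burn_in=burn)
        support = np.flatnonzero(pi > 0)
        # correlated samples: inflate the binomial SE by the relaxation time
        tau = 1.0 / (1.0 - 0.5)  # spectral gap of Moran-K4 is 1/2
        for s in support:
            se = math.sqrt(pi[s] * (1 - pi[s]) * tau / steps)
            assert abs(emp[s] - pi[s]) <= 4 * se


class TestIntersectionFamily:
    MU = [1 / 3, 1 / 3, 1 / 3]

    def test_exact_enumeration(self):
        family, spec = intersection_family(2, 2, [0.25, 0.5, 0.25])
        assert len(family) == 2 * 4
        assert family.weights.sum() == pytest.approx(1.0)

    def test_weight_formula(self):
        family, spec = intersection_family(2, 2, [0.2, 0.5, 0.3])
        # weights grouped by |A|: mu(k) / (n * C(N,k))
        got = sorted(set(np.round(family.weights, 12)))
        expected = sorted({0.2 / 2, 0.5 / (2 * 2), 0.3 / 2})
        assert got == pytest.approx(expected)

    def test_spectral_gap_one_over_n_independent_of_mu(self):
        for mu in (self.MU, [0.5, 0.25, 0.25]):
            family, spec = intersection_family(3, 2, mu)
            spectrum = family_spectrum(family)
            assert 1.0 - spectrum.lambda_star == pytest.approx(1 / 3, abs=1e-10)
            assert spec.spectral_gap == pytest.approx(1 / 3)

    def test_numeric_eigenvalues_group_at_k_over_n(self):
        family, _ = intersection_family(3, 2, self.MU)
        P = transition_matrix(family).P
        numeric = np.sort(np.linalg.eigvals(P).real)[::-1]
        spectrum = family_spectrum(family)
        assert np.allclose(numeric, spectrum.eigenvalues_multiset(), atol=1e-9)
        assert {round(v, 12) for v, _ in spectrum.grouped()} <= {
            round(k / 3, 12) for k in range(4)
        }

    def test_full_support_mu_makes_every_subset_a_chamber(self):
        _, spec = intersection_family(2, 2, [0.25, 0.5, 0.25])
        assert spec.chamber_count == 2 ** (2 * 2)
        _, spec0 = intersection_family(2, 2, [0.5, 0.5, 0.0])
        assert spec0.chamber_count is None

    def test_size_guard_points_to_lazy_mode(self):
        with pytest.raises(ValueError, match="lazy"):
            intersection_family(200, 10, [1 / 11] * 11)

    def test_lazy_sampler_matches_exact_distribution(self):
        exact, spec = intersection_family(2, 2, [0.2, 0.5, 0.3])
        sampler, _ = intersection_family(2, 2, [0.2, 0.5, 0.3], mode="lazy")
        traj = simulate_sampler(sampler, spec.host.empty_subset, 20_000, seed=5)
        emp = traj.empirical_distribution(burn_in=500)
        T = transition_matrix(exact)
        pi = stationary_numeric(T)
        assert np.abs(emp - pi).max() < 0.02
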