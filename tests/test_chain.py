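"""Transition matrices, stationary laws, simulation, total variation, and
mixing-time guarantees."""

import math

import numpy as np
import pytest

from editchains import (
    EditFamily,
    identity_edit,
    mixing_bound,
    moran_family,
    simple_spectrum,
    simulate,
    stationary_numeric,
    stationary_simple,
    transition_matrix,
    tv_decay_bound,
    tv_distance,
    tv_from_stationary,
)
from conftest import path_host


class TestTransitionMatrix:
    def test_worked_example_row_from_full_state(self, simple_p3_quarter):
        host, p, family = simple_p3_quarter
        P = transition_matrix(family).P
        # states by bitmask: 3 = {a,b}, 1 = {a}, 2 = {b}, 0 = empty
        assert P[3, [3, 1, 2, 0]] == pytest.approx([0.25, 0.375, 0.375, 0.0])

    def test_rows_sum_to_one(self, k4):
        family, _ = moran_family(k4)
        P = transition_matrix(family).P
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_simple_process_detailed_balance(self, k3):
        p = np.array([0.2, 0.6, 0.9])
        P = transition_matrix(EditFamily.simple_process(k3, p)).P
        pi = stationary_simple(k3, p)
        assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-14)

    def test_duplicate_edits_merged_with_warning(self, p3):
        from editchains.edits import simple_edit

        e = simple_edit(p3, 0, "+")
        with pytest.warns(UserWarning, match="duplicate"):
            fam = EditFamily([e, e], [0.5, 0.5])
        assert len(fam) == 1 and fam.weights[0] == pytest.approx(1.0)

    def test_dense_guard(self):
        host = path_host(15)
        p = np.full(15, 0.5)
        with pytest.raises(ValueError, match="simulate"):
            transition_matrix(EditFamily.simple_process(host, p))


class TestStationary:
    def test_worked_example_product_form(self, p3_quarter):
        host, p = p3_quarter
        pi = stationary_simple(host, p)
        assert pi[[3, 1, 2, 0]] == pytest.approx([0.0625, 0.1875, 0.1875, 0.5625])

    def test_edge_marginals(self, k4):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, k4.m)
        pi = stationary_simple(k4, p)
        states = np.arange(1 << k4.m)
        for e in range(k4.m):
            marginal = pi[(states >> e) & 1 == 1].sum()
            assert marginal == pytest.approx(p[e], abs=1e-12)

    def test_left_invariance(self, simple_p3_quarter):
        host, p, family = simple_p3_quarter
        P = transition_matrix(family).P
        pi = stationary_simple(host, p)
        assert np.allclose(pi @ P, pi, atol=1e-10)

    def test_numeric_matches_product_form(self, simple_p3_quarter):
        host, p, family = simple_p3_quarter
        T = transition_matrix(family)
        assert np.allclose(stationary_numeric(T), stationary_simple(host, p), atol=1e-12)

    def test_numeric_supported_on_moran_chambers(self, k4):
        from editchains import chambers, generate_semigroup

        family, _ = moran_family(k4)
        T = transition_matrix(family)
        pi = stationary_numeric(T)
        _, mapping = chambers(generate_semigroup(list(family.edits)))
        chamber_states = {s.bits for s in mapping.values()}
        assert set(np.flatnonzero(pi > 0)) == chamber_states

    def test_identity_family_rejected(self, p3):
        fam = EditFamily([identity_edit(p3)], [1.0])
        T = transition_matrix(fam)
        with pytest.raises(ValueError, match="recurrent classes"):
            stationary_numeric(T)


class TestSimulate:
    def test_zero_steps(self, simple_p3_quarter):
        host, p, family = simple_p3_quarter
        traj = simulate(family, host.full_subset, 0, seed=1)
        assert list(traj.states) == [3]

    def test_same_seed_same_trajectory(self, simple_p3_quarter):
        host, p, family = simple_p3_quarter
        a = simulate(family, host.empty_subset, 500, seed=42)
        b = simulate(family, host.empty_subset, 500, seed=42)
        assert np.array_equal(a.states, b.states)

    def test_long_run_edge_frequency_matches_marginal(self, simple_p3_quarter):
        host, p, family = simple_p3_quarter
        steps, burn = 10**5, 10**3
        traj = simulate(family, host.empty_subset, steps, seed=7)
        freq = np.mean((traj.states[burn:] & 1) == 1)
        # edge indicator flips at rate 1/m, so the integrated autocorrelation
        # time is 2m - 1; use the correspondingly inflated standard error
        se = math.sqrt(0.25 * 0.75 * (2 * host.m - 1) / steps)
        assert abs(freq - 0.25) <= 3 * se


class TestTotalVariation:
    def test_identical_distributions(self):
        mu = np.array([0.25, 0.75])
        assert tv_distance(mu, mu) == 0.0

    def test_disjoint_point_masses(self):
        assert tv_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_uniform_vs_point_mass(self):
        assert tv_distance(np.full(4, 0.25), np.array([1.0, 0, 0, 0])) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tv_distance(np.ones(2) / 2, np.ones(3) / 3)


class TestDecayBound:
    def test_t0_counts_chambers_minus_one(self):
        assert tv_decay_bound(0, simple_spectrum(4)) == 2**4 - 1

    def test_dominated_by_closed_form_envelope(self):
        m = 5
        spec = simple_spectrum(m)
        t = math.ceil(2 * m * math.log(m))
        assert tv_decay_bound(t, spec) <= 2 * m * (1 - 1 / m) ** t + 1e-15

    def test_monotone_in_t(self):
        spec = simple_spectrum(3)
        vals = [tv_decay_bound(t, spec) for t in range(0, 20)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_bound_dominates_exact_tv(self, m):
        host = path_host(m)
        rng = np.random.default_rng(m)
        p = rng.uniform(0.1, 0.9, m)
        P = transition_matrix(EditFamily.simple_process(host, p)).P
        pi = stationary_simple(host, p)
        spec = simple_spectrum(m)
        for t in (0, 1, 2, 5, 10):
            exact = tv_from_stationary(P, pi, t).max()
            assert exact <= tv_decay_bound(t, spec) + 1e-12


class TestMixingBound:
    def test_simple_arithmetic(self):
        assert mixing_bound("simple", m=5, c=1.0) == 22

    def test_compound_arithmetic(self):
        assert mixing_bound("compound", m=6, c=1.0, lambda_star=0.5) == 11

    def test_sharpened_never_worse_when_chambers_bounded(self):
        for m in (3, 5, 8):
            plain = mixing_bound("compound", m=m, c=2.0, lambda_star=0.4)
            sharp = mixing_bound(
                "compound_sharpened", c=2.0, lambda_star=0.4, M=2**m
            )
            assert sharp <= plain

    def test_lambda_star_must_be_below_one(self):
        with pytest.raises(ValueError):
            mixing_bound("compound", m=3, c=1.0, lambda_star=1.0)

    @pytest.mark.parametrize("c", [1.0, 2.0, 3.0])
    @pytest.mark.parametrize("m", [2, 4, 6])
    def test_simple_guarantee_holds_from_every_start(self, m, c):
        host = path_host(m)
        rng = np.random.default_rng(10 * m)
        p = rng.uniform(0.1, 0.9, m)
        P = transition_matrix(EditFamily.simple_process(host, p)).P
        pi = stationary_simple(host, p)
        t = mixing_bound("simple", m=m, c=c)
        assert tv_from_stationary(P, pi, t).max() <= math.exp(-c)
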