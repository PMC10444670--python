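import numpy as np
import pytest
from helpers_oracle import grid_polish, loglik_direct, oracle_common, oracle_groupwise

import loglinsup as ll
from loglinsup.estimation import (
    BoundaryError,
    EmptyGroupError,
    SupportViolationError,
)
from loglinsup.model_specs import ModelSpec


class TestLoglikSaturated:
    @pytest.mark.parametrize("counts,value", [
        ([2, 2], -4 * np.log(2)),
        ([7], 0.0),
        ([4, 3, 2, 1], 4 * np.log(4) + 3 * np.log(3) + 2 * np.log(2) - 10 * np.log(10)),
    ])
    def test_closed_form(self, counts, value):
        assert ll.loglik_saturated(counts) == pytest.approx(value, abs=1e-12)

    def test_zero_counts_contribute_nothing(self):
        assert ll.loglik_saturated([3, 0, 1]) == ll.loglik_saturated([3, 1])


class TestFit:
    def test_saturated_fit_is_observed_proportions(self, toy22):
        O, _, _ = toy22
        res = ll.fit(O, O, ModelSpec("saturated", (2, 2), support=O))
        np.testing.assert_allclose(res.prob_vector(), O.counts() / 10, rtol=0,
                                   atol=1e-14)
        assert res.loglik == pytest.approx(ll.loglik_saturated(O.counts()))

    def test_saturated_zero_cell_is_boundary(self, toy22):
        O, B, _ = toy22
        O2 = ll.observed_support([(0, 0), (0, 1)], (2, 2))
        with pytest.raises(BoundaryError):
            ll.fit(O2, B, ModelSpec("saturated", (2, 2), support=B))

    def test_independence_toy_closed_form(self, toy22):
        """Margin products: fitted counts (4.2, 2.8, 1.8, 1.2) on B = A."""
        O, B, spec = toy22
        res = ll.fit(O, B, spec)
        np.testing.assert_allclose(res.n * res.prob_vector(),
                                   [4.2, 2.8, 1.8, 1.2], atol=1e-8)
        np.testing.assert_allclose(res.theta, [np.log(3 / 7), np.log(4 / 6)],
                                   atol=1e-8)
        assert res.converged

    def test_intercept_only_uniform(self, toy22):
        O, B, _ = toy22
        spec = ModelSpec("custom", (2, 2), row_fn=lambda p: [], custom_e=0)
        res = ll.fit(O, B, spec)
        np.testing.assert_allclose(res.prob_vector(), 0.25, atol=1e-12)

    def test_support_violation(self, toy22):
        O, _, spec = toy22
        B = ll.SupportSet([(0, 0), (0, 1)], (2, 2))
        with pytest.raises(SupportViolationError):
            ll.fit(O, B, spec)

    def test_zero_cells_shape_kappa(self, toy22):
        """B ⊃ O changes the fit even though the extra cells have count 0."""
        O, B, spec = toy22
        O3 = ll.observed_support([(0, 0)] * 4 + [(0, 1)] * 3 + [(1, 0)] * 2,
                                 (2, 2))
        res_O = ll.fit(O3, O3, spec)
        res_A = ll.fit(O3, ll.make_support(O3, "A"), spec)
        assert abs(res_O.loglik - res_A.loglik) > 1e-3

    def test_probability_conservation(self, cner5_sample):
        spec, _, _, _, O = cner5_sample
        res = ll.fit(O, O, spec)
        assert res.prob_vector().sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(res.prob_vector() > 0)
        assert res.n * res.prob_vector().sum() == pytest.approx(res.n, abs=1e-8)

    def test_route_equivalence_newton_vs_poisson(self, cner5_sample):
        """Multinomial and Poisson log-linear routes share estimating equations."""
        spec, _, _, _, O = cner5_sample
        a = ll.fit(O, O, spec, method="newton")
        b = ll.fit(O, O, spec, method="poisson")
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-6)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)

    def test_oracle_equivalence_small_support(self, toy22):
        O, B, spec = toy22
        X = spec.design_matrix(B.patterns)
        counts = np.array([O.freq.get(p, 0) for p in B.patterns], dtype=float)
        th_star, ll_star = grid_polish(X, counts)
        res = ll.fit(O, B, spec)
        np.testing.assert_allclose(res.theta, th_star, atol=1e-4)
        assert res.loglik == pytest.approx(ll_star, abs=1e-6)

    def test_aliased_column_dropped_and_reported(self):
        """A variable constant on B is non-estimable; effective e shrinks."""
        rows = [(0, 0), (0, 0), (0, 1), (0, 1), (0, 1)]
        O = ll.observed_support(rows, (2, 2))
        spec = ModelSpec("two_way", (2, 2), order=1)
        res = ll.fit(O, O, spec)
        assert res.e_nominal == 2
        assert res.e_effective == 1
        assert not res.estimable_mask[0]       # y1 never varies
        assert np.isnan(res.theta[0]) and np.isnan(res.se[0])


class TestLoglikIdentity:
    def test_nested_support_likelihood_ratio_identity(self, cner5_sample):
        """l_B(θ) = l_S(θ) − n·ln P(B) with P(B) = κ_B/κ_S, any θ."""
        spec, theta0, S, _, O = cner5_sample
        rng = np.random.default_rng(11)
        B = O
        XS = spec.design_matrix(S.patterns)
        XB = spec.design_matrix(B.patterns)
        for _ in range(5):
            th = theta0 + rng.normal(0, 0.5, size=spec.e)
            kappa_S = np.exp(XS @ th).sum()
            kappa_B = np.exp(XB @ th).sum()
            lB = ll.loglik_value(th, O, B, spec)
            lS = ll.loglik_value(th, O, S, spec)
            assert lB == pytest.approx(lS - O.n * np.log(kappa_B / kappa_S),
                                       abs=1e-10)


class TestStandardErrors:
    def test_matches_finite_difference_hessian(self, toy22):
        """SEs equal sqrt(diag inv(−numeric Hessian of the log-likelihood))."""
        O, B, spec = toy22
        res = ll.fit(O, B, spec)
        X = spec.design_matrix(B.patterns)
        counts = np.array([O.freq.get(p, 0) for p in B.patterns], dtype=float)
        th = res.theta
        h = 1e-5
        e = len(th)
        H = np.zeros((e, e))
        for i in range(e):
            for j in range(e):
                pp = th.copy(); pp[i] += h; pp[j] += h
                pm = th.copy(); pm[i] += h; pm[j] -= h
                mp = th.copy(); mp[i] -= h; mp[j] += h
                mm = th.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = (loglik_direct(pp, X, counts)
                           - loglik_direct(pm, X, counts)
                           - loglik_direct(mp, X, counts)
                           + loglik_direct(mm, X, counts)) / (4 * h * h)
        se_num = np.sqrt(np.diag(np.linalg.inv(-H)))
        np.testing.assert_allclose(res.se, se_num, atol=1e-6)

    def test_recompute_matches_fit(self, cner5_sample):
        spec, _, _, _, O = cner5_sample
        res = ll.fit(O, O, spec)
        np.testing.assert_allclose(ll.standard_errors(res), res.se, atol=1e-12)


class TestGroupwise:
    def test_matches_brute_force(self, toy22, parity_partition):
        O, B, spec = toy22
        gw = ll.fit_groupwise(O, parity_partition, spec)
        Xs = [spec.design_matrix(g.patterns)[:, f.estimable_mask]
              for g, f in zip(parity_partition.groups, gw.fits)]
        cs = [np.array([O.freq.get(p, 0) for p in g.patterns], dtype=float)
              for g in parity_partition.groups]
        _, ll_star = oracle_groupwise(Xs, cs)
        assert gw.loglik_model == pytest.approx(ll_star, abs=1e-6)
        n_p = np.array(gw.n_p, dtype=float)
        assert gw.loglik_total == pytest.approx(
            ll_star + float(n_p @ np.log(n_p / n_p.sum())), abs=1e-6)
        np.testing.assert_allclose(gw.pi, n_p / n_p.sum())

    def test_zero_observation_group_rejected(self, toy22):
        O, B, spec = toy22
        O3 = ll.observed_support([(0, 0)] * 4 + [(0, 1)] * 3 + [(1, 0)] * 2,
                                 (2, 2))
        part = ll.Partition([B.restrict([(0, 0), (0, 1), (1, 0)]),
                             B.restrict([(1, 1)])], "manual", B)
        with pytest.raises(EmptyGroupError):
            ll.fit_groupwise(O3, part, spec)

    def test_common_theta_matches_brute_force(self, toy22, parity_partition):
        O, B, spec = toy22
        ct = ll.fit_common_theta(O, parity_partition, spec)
        Xs = [spec.design_matrix(g.patterns)[:, ct.estimable_mask]
              for g in parity_partition.groups]
        cs = [np.array([O.freq.get(p, 0) for p in g.patterns], dtype=float)
              for g in parity_partition.groups]
        _, ll_star = oracle_common(Xs, cs)
        assert ct.loglik_model == pytest.approx(ll_star, abs=1e-6)

    def test_nested_likelihood_ordering(self, cner5_sample):
        """ln L̂_B ≤ ln L̂_C + Σ n_p ln(n_p/n) ≤ groupwise total."""
        spec, _, _, _, O = cner5_sample
        part = ll.partition_support(O, "random", g=2, seed=5)
        base = ll.fit(O, O, spec)
        gw = ll.fit_groupwise(O, part, spec)
        ct = ll.fit_common_theta(O, part, spec)
        assert base.loglik <= ct.loglik_total + 1e-8
        assert ct.loglik_total <= gw.loglik_total + 1e-8
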