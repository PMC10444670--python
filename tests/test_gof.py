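import numpy as np
import pytest
from helpers_oracle import grid_polish, oracle_common, oracle_groupwise

import loglinsup as ll
from loglinsup.gof import SparseCellError, SparseCellWarning
from loglinsup.model_specs import ModelSpec


@pytest.fixture
def toy_fit(toy22):
    O, B, spec = toy22
    return O, B, spec, ll.fit(O, B, spec)


class TestClassicalTests:
    def test_saturated_fit_perfect(self, toy22):
        O, _, _ = toy22
        res = ll.fit(O, O, ModelSpec("saturated", (2, 2), support=O))
        cs = ll.pearson_test(res, O, force=True)
        assert cs.statistic == pytest.approx(0.0, abs=1e-10)
        assert cs.df == 0 and cs.p_value == 1.0
        lrs = ll.lr_saturated_test(res, O, force=True)
        assert lrs.statistic == pytest.approx(0.0, abs=1e-10)

    def test_independence_toy_statistics(self, toy_fit):
        """Hand expansion against margin-product fitted counts (4.2,2.8,1.8,1.2)."""
        O, B, spec, res = toy_fit
        obs = np.array([4, 3, 2, 1], dtype=float)
        exp = np.array([4.2, 2.8, 1.8, 1.2])
        cs = ll.pearson_test(res, O, force=True)
        assert cs.statistic == pytest.approx(np.sum((obs - exp) ** 2 / exp),
                                             abs=1e-8)
        assert cs.statistic == pytest.approx(0.0794, abs=2e-4)
        assert cs.df == 1
        lrs = ll.lr_saturated_test(res, O, force=True)
        assert lrs.statistic == pytest.approx(
            2 * np.sum(obs * np.log(obs / exp)), abs=1e-8)
        assert lrs.statistic == pytest.approx(0.0804, abs=2e-4)
        assert lrs.df == cs.df

    def test_sparse_gate_refuses_then_warns(self, toy_fit):
        O, B, spec, res = toy_fit
        with pytest.raises(SparseCellError):
            ll.pearson_test(res, O)
        with pytest.warns(SparseCellWarning):
            ll.pearson_test(res, O, force=True)

    def test_cs_lrs_first_order_agreement(self):
        """With all expected counts >= 10 the two statistics are close."""
        rng = np.random.default_rng(2)
        spec, th0 = ll.build_cn_er(4, betas=(-0.5, -0.25, 0.25, 0.5), sigma2=0.2)
        S = ll.enumerate_full_support((2,) * 4)
        data = ll.sample_dataset(ll.GeneratorConfig(spec, th0, S, 2000), rng=rng)
        O = ll.observed_support(data, (2,) * 4)
        res = ll.fit(O, O, spec)
        cs = ll.pearson_test(res, O)
        lrs = ll.lr_saturated_test(res, O)
        assert min(res.n * res.prob_vector()) >= 10
        assert abs(cs.statistic - lrs.statistic) / cs.statistic <= 0.2


class TestPartitionTests:
    def test_df_formulas(self, cner5_sample):
        spec, _, _, _, O = cner5_sample
        part = ll.partition_support(O, "random", g=2, seed=1)
        res = ll.fit(O, O, spec)
        gw = ll.fit_groupwise(O, part, spec)
        ct = ll.fit_common_theta(O, part, spec)
        lr1 = ll.lr_test_first_gen(res, gw)
        lr2 = ll.lr_test_second_gen(res, ct)
        lr12 = ll.lr_test_gen1_vs_gen2(gw, ct)
        assert lr1.df_nominal == (2 - 1) * (spec.e + 1)
        assert lr2.df_nominal == 2 - 1
        assert lr12.df_nominal == (2 - 1) * spec.e
        # with g=2 and e=34 the nominal first-generalization df is 35
        assert (2 - 1) * (ModelSpec("epcm", (5,) * 7).e + 1) == 35

    def test_additivity_identity(self, cner5_sample):
        """LR1 = LR2 + LR12 and df adds, for several partitions."""
        spec, _, _, _, O = cner5_sample
        res = ll.fit(O, O, spec)
        for seed in (1, 2, 3):
            part = ll.partition_support(O, "random", g=2, seed=seed)
            gw = ll.fit_groupwise(O, part, spec)
            ct = ll.fit_common_theta(O, part, spec)
            lr1 = ll.lr_test_first_gen(res, gw)
            lr2 = ll.lr_test_second_gen(res, ct)
            lr12 = ll.lr_test_gen1_vs_gen2(gw, ct)
            assert lr1.statistic == pytest.approx(
                lr2.statistic + lr12.statistic, abs=1e-8)
            assert lr1.df == lr2.df + lr12.df

    def test_parity_partition_matches_brute_force(self, toy22, parity_partition):
        O, B, spec = toy22
        res = ll.fit(O, B, spec)
        gw = ll.fit_groupwise(O, parity_partition, spec)
        ct = ll.fit_common_theta(O, parity_partition, spec)
        lr1 = ll.lr_test_first_gen(res, gw)
        lr2 = ll.lr_test_second_gen(res, ct)
        lr12 = ll.lr_test_gen1_vs_gen2(gw, ct)

        X = spec.design_matrix(B.patterns)
        counts = np.array([O.freq.get(p, 0) for p in B.patterns], dtype=float)
        _, ll_B = grid_polish(X, counts)
        Xs = [spec.design_matrix(g.patterns)[:, f.estimable_mask]
              for g, f in zip(parity_partition.groups, gw.fits)]
        cs = [np.array([O.freq.get(p, 0) for p in g.patterns], dtype=float)
              for g in parity_partition.groups]
        _, ll_gw = oracle_groupwise(Xs, cs)
        Xs_c = [spec.design_matrix(g.patterns)[:, ct.estimable_mask]
                for g in parity_partition.groups]
        _, ll_ct = oracle_common(Xs_c, cs)
        n_p = np.array([c.sum() for c in cs])
        memb = float(n_p @ np.log(n_p / n_p.sum()))
        assert lr1.statistic == pytest.approx(-2 * (ll_B - (ll_gw + memb)),
                                              abs=1e-4)
        assert lr2.statistic == pytest.approx(-2 * (ll_B - (ll_ct + memb)),
                                              abs=1e-4)
        assert lr12.statistic == pytest.approx(-2 * (ll_ct - ll_gw), abs=1e-4)

    def test_saturated_groups_recover_saturated_lr(self, toy22):
        """Per-group saturated alternatives reduce LR1 to the saturated LR test."""
        O, B, spec = toy22
        res = ll.fit(O, B, spec)
        part = ll.partition_support(B, "weighted_sum", w=[1, 1])
        gw = ll.fit_groupwise(O, part, ModelSpec("saturated", (2, 2), support=B))
        lr1 = ll.lr_test_first_gen(res, gw)
        lrs = ll.lr_saturated_test(res, O, force=True)
        assert lr1.statistic == pytest.approx(lrs.statistic, abs=1e-8)

    def test_invariance_to_pattern_reordering(self, toy22):
        O, B, spec = toy22
        perm = [(1, 0), (0, 0), (1, 1), (0, 1)]
        B2 = ll.SupportSet(perm, (2, 2), {p: B.freq[p] for p in perm})
        r1 = ll.fit(O, B, spec)
        r2 = ll.fit(O, B2, spec)
        a = ll.pearson_test(r1, O, force=True).statistic
        b = ll.pearson_test(r2, O, force=True).statistic
        assert a == pytest.approx(b, abs=1e-8)

    def test_rasch_total_score_partition_runs(self):
        """Extended Rasch on B=A with total-score groups: the Andersen setup."""
        rng = np.random.default_rng(8)
        spec, th0 = ll.build_cn_er(4, betas=(-1.0, -0.5, 0.0, 0.5), sigma2=0.3)
        S = ll.enumerate_full_support((2,) * 4)
        data = ll.sample_dataset(ll.GeneratorConfig(spec, th0, S, 500), rng=rng)
        O = ll.observed_support(data, (2,) * 4)
        B = ll.make_support(O, "A")
        rasch = ModelSpec("extended_rasch", (2,) * 4)
        res = ll.fit(O, B, rasch)
        part = ll.partition_support(B, "weighted_sum", w=[1] * 4)
        gw = ll.fit_groupwise(O, part, rasch)
        ct = ll.fit_common_theta(O, part, rasch)
        lr12 = ll.lr_test_gen1_vs_gen2(gw, ct)
        assert lr12.statistic >= 0
        assert 0 <= lr12.p_value <= 1
        # within a total-score group every association column is constant,
        # so only the item main effects can differ between groups
        assert all(f.e_effective <= 4 for f in gw.fits)
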