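"""Tests of the NB-GLM and CLR Monte-Carlo differential-abundance engines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from compda.da_tests import (
    LENIENT, STRINGENT, CallPolicy, bh_adjust, call_features, clr_mc_test,
    nb_glm_test, run_method,
)
from compda.simulate import SimulationConfig, simulate_dataset


def brute_force_bh(p):
    """Quadratic-time BH step-up oracle."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    q = np.empty(n)
    for i in range(n):
        rank = np.sum(p <= p[i])
        candidates = [p[j] * n / np.sum(p <= p[j])
                      for j in range(n) if p[j] >= p[i]]
        q[i] = min(min(candidates), 1.0)
        del rank
    return q


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=30), st.randoms(use_true_random=False))
    def test_order_invariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        assert np.allclose([q[i] for i in perm], q_perm)


class TestCallPolicy:
    def test_threshold_edge_called(self):
        res = pd.DataFrame({"q": [0.049], "log2fc": [0.3]})
        assert call_features(res, LENIENT).all()

    def test_effect_size_gate(self):
        res = pd.DataFrame({"q": [0.001], "log2fc": [0.5]})
        assert not call_features(res, CallPolicy(0.05, 1.0)).any()

    def test_stringent_policy_never_adds_calls(self):
        rng = np.random.default_rng(0)
        res = pd.DataFrame({"q": rng.random(200),
                            "log2fc": rng.normal(0, 2, 200)})
        lenient = call_features(res, LENIENT)
        stringent = call_features(res, STRINGENT)
        assert not np.any(stringent & ~lenient)

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            CallPolicy(fdr=0.0)


class TestNBGLM:
    def test_null_p_values_are_uniform(self):
        # 2000 null features, large replicate number: KS test at alpha=0.01
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(50, 50 / (50 + 100), size=(2000, 100))
        condition = np.repeat([1, 2], 50)
        res = nb_glm_test(counts, condition)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_log2fc_recovered(self):
        # group means 100 vs 400 at NB size 1000, R=10: log2fc ~ 2
        rng = np.random.default_rng(1)
        mu = np.concatenate([np.full(10, 100.0), np.full(10, 400.0)])
        counts = rng.negative_binomial(1000, 1000 / (1000 + mu),
                                       size=(200, 20))
        res = nb_glm_test(counts, np.repeat([1, 2], 10))
        assert np.median(res["log2fc"]) == pytest.approx(2.0, abs=0.1)

    def test_all_zero_feature_not_called(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, size=(5, 8))
        counts[0] = 0
        res = nb_glm_test(counts, np.repeat([1, 2], 4))
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "log2fc"] == 0.0
        assert not res.loc[0, "called"]
        assert res.loc[0, "flag"] == "all_zero"

    def test_one_group_all_zero_is_flagged_and_detected(self):
        counts = np.column_stack([np.zeros((1, 5)), np.full((1, 5), 200)])
        counts = np.vstack([counts, np.full((1, 10), 50)])
        res = nb_glm_test(counts.astype(int), np.repeat([1, 2], 5))
        assert res.loc[0, "flag"] == "zero_group"
        assert res.loc[0, "q"] < 0.05

    def test_size_factor_offsets_remove_depth_effect(self):
        # doubling half the samples is absorbed by matching size factors
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=(300, 10))
        counts = np.column_stack([base[:, :5], 4 * base[:, 5:]])
        sf = np.array([1.0] * 5 + [4.0] * 5)
        res = nb_glm_test(counts, np.repeat([1, 2], 5), size_factors=sf)
        assert (res["q"] < 0.05).mean() < 0.02

    def test_oracle_recovers_large_effects(self):
        # >= 4-fold perturbations at R=10 should be nearly all detected
        cfg = SimulationConfig(P=300, m=5.0, S=1.0, a=0.0, c=0.0, g=0.1,
                               seed=10)
        data = simulate_dataset(cfg)
        truth = np.zeros(300, dtype=bool)
        truth[:100] = True
        Y = data.Y.copy()
        Y[truth][:, data.condition == 2]  # no-op guard
        Y[:100, data.condition == 2] *= 4
        res = nb_glm_test(Y, data.condition)
        sens = res["called"].to_numpy()[truth].mean()
        assert sens > 0.95


class TestCLRMonteCarlo:
    def test_identical_groups_call_nothing(self):
        rng = np.random.default_rng(9)
        col = rng.integers(5, 500, size=100)
        Z = np.tile(col[:, None], (1, 8))
        res = clr_mc_test(Z, np.repeat([1, 2], 4),
                          rng=np.random.default_rng(0))
        # instance-averaged BH values concentrate near 1 under the null
        assert np.all(res["q"] > 0.8)
        assert not res["called"].any()

    def test_spiked_feature_has_smallest_q(self):
        rng = np.random.default_rng(7)
        base = rng.integers(50, 200, size=100).astype(float)
        cols = []
        for j in range(20):
            lam = base.copy()
            if j >= 10:
                lam[0] *= 16.0
            cols.append(rng.poisson(lam))
        Z = np.column_stack(cols)
        res = clr_mc_test(Z, np.repeat([1, 2], 10),
                          rng=np.random.default_rng(1))
        assert res["q"].idxmin() == 0

    def test_depth_rescaling_preserves_calls(self):
        rng = np.random.default_rng(8)
        base = rng.integers(20, 300, size=60).astype(float)
        cols = []
        for j in range(12):
            lam = base.copy()
            if j >= 6:
                lam[:10] *= 8.0
            cols.append(rng.poisson(lam))
        Z = np.column_stack(cols)
        res1 = clr_mc_test(Z, np.repeat([1, 2], 6),
                           rng=np.random.default_rng(5))
        res2 = clr_mc_test(2 * Z, np.repeat([1, 2], 6),
                           rng=np.random.default_rng(5))
        assert np.array_equal(res1["called"], res2["called"])

    def test_requires_two_instances(self):
        Z = np.ones((4, 6), dtype=int)
        with pytest.raises(ValueError):
            clr_mc_test(Z, np.repeat([1, 2], 3), n_mc=1)


class TestRunMethod:
    def test_unknown_method_rejected(self):
        Z = np.ones((4, 6), dtype=int)
        with pytest.raises(ValueError):
            run_method(Z, np.repeat([1, 2], 3), "voom")

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(P=100, m=4.0, S=1.0, a=2.0, c=0.5, g=0.2,
                               seed=6)
        data = simulate_dataset(cfg)
        r1 = run_method(data.Z, data.condition, "clr_mc",
                        rng=np.random.default_rng(3), n_mc=16)
        r2 = run_method(data.Z, data.condition, "clr_mc",
                        rng=np.random.default_rng(3), n_mc=16)
        pd.testing.assert_frame_equal(r1, r2)

    def test_oracle_null_calibration_raw_p(self):
        # c=0, g=0: exchangeable conditions, so the oracle's raw p-values
        # should flag ~5% of features at the 0.05 level
        fracs = []
        for seed in range(4):
            cfg = SimulationConfig(P=400, m=5.0, S=1.0, a=0.0, c=0.0, g=0.0,
                                   seed=seed)
            data = simulate_dataset(cfg)
            res = run_method(data.Y, data.condition, "oracle_glm")
            fracs.append((res["p"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)

    def test_tmm_beats_total_count_under_compositional_change(self):
        # one-sided perturbation: rescaling should cut false positives
        cfg = SimulationConfig(P=400, m=5.0, S=1.0, a=4.0, c=0.7, g=0.1,
                               seed=13)
        data = simulate_dataset(cfg)
        oracle = run_method(data.Y, data.condition, "oracle_glm")
        o = oracle["called"].to_numpy()
        fp = {}
        for method in ("tmm_glm", "total_glm"):
            res = run_method(data.Z, data.condition, method)
            fp[method] = int(np.sum(~o & res["called"].to_numpy()))
        assert fp["tmm_glm"] < fp["total_glm"]
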