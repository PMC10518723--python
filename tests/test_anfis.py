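"""Five-layer ANFIS: membership functions, rule base, forward pass,
hybrid learning."""

import dataclasses
import math

import numpy as np
import pytest

from anfisbpso import anfis, synthetic
from anfisbpso.anfis import (
    GAUSSIAN,
    GBELL,
    AnfisConfig,
    MembershipFunction,
)
from anfisbpso.errors import ParameterError, RuleExplosionError


class TestMembership:
    @pytest.mark.parametrize(
        "mf,x,expected",
        [
            (MembershipFunction(GBELL, (1.0, 1.0, 0.0)), 0.0, 1.0),
            (MembershipFunction(GBELL, (1.0, 1.0, 0.0)), 1.0, 0.5),
            (MembershipFunction(GBELL, (2.0, 3.0, 1.0)), 1.0, 1.0),
            (MembershipFunction(GAUSSIAN, (1.0, 0.0)), 0.0, 1.0),
            (MembershipFunction(GAUSSIAN, (1.0, 0.0)), 1.0, math.exp(-0.5)),
        ],
    )
    def test_pointwise_values(self, mf, x, expected):
        assert anfis.eval_membership(mf, x) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_about_center(self):
        mf = MembershipFunction(GBELL, (0.7, 1.3, 0.4))
        xs = np.linspace(0, 2, 17)
        np.testing.assert_allclose(mf(0.4 + xs), mf(0.4 - xs))

    def test_range_is_unit_interval(self, rng):
        mf = MembershipFunction(GAUSSIAN, (0.3, 0.5))
        vals = mf(rng.normal(size=100))
        assert np.all(vals > 0) and np.all(vals <= 1)

    @pytest.mark.parametrize(
        "kind,params",
        [(GBELL, (-1.0, 1.0, 0.0)), (GBELL, (1.0, 0.0, 0.0)), (GAUSSIAN, (0.0, 0.0))],
    )
    def test_invalid_params_raise(self, kind, params):
        with pytest.raises(ParameterError):
            MembershipFunction(kind, params)


class TestGridPartition:
    @pytest.mark.parametrize("n_inputs,n_mfs,expected", [(5, 2, 32), (1, 3, 3), (3, 3, 27)])
    def test_rule_count_is_power(self, n_inputs, n_mfs, expected):
        assert anfis.grid_partition(n_inputs, n_mfs).n_rules == expected

    def test_lexicographic_enumeration(self):
        rb = anfis.grid_partition(2, 2)
        np.testing.assert_array_equal(rb.rules, [[0, 0], [0, 1], [1, 0], [1, 1]])

    def test_cap_raises(self):
        with pytest.raises(RuleExplosionError):
            anfis.grid_partition(10, 4, rule_cap=1000)

    def test_premise_tiles_unit_interval(self):
        model = anfis.build_model(2, AnfisConfig(n_mfs=3))
        np.testing.assert_allclose(model.premise[0, :, 2], [0.0, 0.5, 1.0])


class TestForward:
    def test_single_rule_intercept_only(self):
        model = anfis.build_model(1, AnfisConfig(n_mfs=1))
        model = dataclasses.replace(model, consequent=np.array([[0.0, 7.5]]))
        W, Wn, out = anfis.forward(model, np.array([0.5]))
        assert Wn[0] == pytest.approx(1.0)
        assert out == pytest.approx(7.5)

    def test_symmetric_input_splits_weight_evenly(self):
        model = anfis.build_model(1, AnfisConfig(n_mfs=2))
        _, Wn, _ = anfis.forward(model, np.array([0.5]))
        np.testing.assert_allclose(Wn, [0.5, 0.5])

    def test_matches_layer_by_layer_oracle(self, toy_model, rng):
        """Independent per-layer evaluation with explicit loops."""
        x = rng.uniform(0, 1, size=2)
        W, Wn, out = anfis.forward(toy_model, x)
        mfs = [
            [
                MembershipFunction(GBELL, tuple(toy_model.premise[j, k]))
                for k in range(2)
            ]
            for j in range(2)
        ]
        w_o = np.array(
            [
                mfs[0][r0](x[0]) * mfs[1][r1](x[1])
                for r0, r1 in toy_model.rulebase.rules
            ]
        )
        wn_o = w_o / w_o.sum()
        out_o = sum(
            wn_o[r] * (toy_model.consequent[r, :2] @ x + toy_model.consequent[r, 2])
            for r in range(4)
        )
        np.testing.assert_allclose(W, w_o, atol=1e-14)
        np.testing.assert_allclose(Wn, wn_o, atol=1e-14)
        assert out == pytest.approx(out_o, abs=1e-12)

    def test_normalized_strengths_sum_to_one(self, toy_model, rng):
        X = rng.uniform(0, 1, size=(50, 2))
        _, Wn, _ = anfis.forward(toy_model, X)
        np.testing.assert_allclose(Wn.sum(axis=1), 1.0, atol=1e-12)

    def test_all_ones_mask_bitwise_identical_to_unmasked_computation(
        self, toy_model, rng
    ):
        X = rng.uniform(0, 1, size=(20, 2))
        W, Wn, out = anfis.forward(toy_model, X)
        # recompute with the masking multiply removed entirely
        M = anfis.membership_matrix(toy_model, X)
        W_nomask = np.ones((20, 4))
        for j in range(2):
            W_nomask *= M[:, j, toy_model.rulebase.rules[:, j]]
        Wn_nomask = W_nomask / W_nomask.sum(axis=1, keepdims=True)
        out_nomask = (Wn_nomask * anfis.rule_outputs(toy_model, X)).sum(axis=1)
        assert np.array_equal(W, W_nomask)
        assert np.array_equal(Wn, Wn_nomask)
        assert np.array_equal(out, out_nomask)

    def test_wrong_input_width_raises(self, toy_model):
        with pytest.raises(ValueError, match="2"):
            anfis.forward(toy_model, np.zeros(3))


class TestLse:
    def test_recovers_generating_consequents(self):
        data, gen = synthetic.generate_sugeno(2, 2, seed=7, n_samples=300)
        blank = dataclasses.replace(gen, consequent=np.zeros_like(gen.consequent))
        solved = anfis.lse_consequent(blank, data.X, data.y)
        np.testing.assert_allclose(solved.consequent, gen.consequent, atol=1e-6)

    def test_zero_targets_give_zero_coefficients(self, toy_model, rng):
        X = rng.uniform(0, 1, size=(10, 2))
        solved = anfis.lse_consequent(toy_model, X, np.zeros(10))
        np.testing.assert_allclose(solved.consequent, 0.0, atol=1e-12)

    def test_single_sample_single_rule_interpolates(self):
        model = anfis.build_model(1, AnfisConfig(n_mfs=1))
        X, y = np.array([[0.3]]), np.array([2.0])
        solved = anfis.lse_consequent(model, X, y)
        assert anfis.predict(solved, X)[0] == pytest.approx(2.0, abs=1e-12)

    def test_never_increases_training_mse(self, toy_model, rng):
        X = rng.uniform(0, 1, size=(40, 2))
        y = rng.normal(size=40)
        before = anfis.training_mse(toy_model, X, y)
        after = anfis.training_mse(anfis.lse_consequent(toy_model, X, y), X, y)
        assert after <= before + 1e-12

    def test_masked_rules_get_zero_coefficients(self, toy_model, rng):
        X = rng.uniform(0, 1, size=(30, 2))
        y = rng.normal(size=30)
        masked = anfis.lse_consequent(
            toy_model.with_mask(np.array([1, 0, 1, 0])), X, y
        )
        np.testing.assert_array_equal(masked.consequent[[1, 3]], 0.0)

    def test_empty_sample_set_raises(self, toy_model):
        with pytest.raises(ValueError):
            anfis.lse_consequent(toy_model, np.empty((0, 2)), np.empty(0))


class TestPremiseGradient:
    def test_zero_lr_leaves_parameters(self, toy_model, rng):
        X = rng.uniform(0, 1, size=(15, 2))
        out = anfis.gd_premise_step(toy_model, X, rng.normal(size=15), lr=0.0)
        np.testing.assert_array_equal(out.premise, toy_model.premise)

    @pytest.mark.parametrize("mf_kind", [GBELL, GAUSSIAN])
    def test_analytic_matches_central_differences(self, mf_kind, rng):
        model = anfis.build_model(2, AnfisConfig(n_mfs=2, mf_kind=mf_kind))
        X = rng.uniform(0, 1, size=(25, 2))
        y = rng.normal(size=25)
        model = anfis.lse_consequent(model, X, y)
        ga = anfis._premise_gradient_analytic(model, X, y)
        gf = anfis._premise_gradient_fd(model, X, y, h=1e-6)
        np.testing.assert_allclose(ga, gf, rtol=1e-4, atol=1e-8)

    def test_small_step_descends(self, rng):
        model = anfis.build_model(1, AnfisConfig(n_mfs=2))
        premise = model.premise.copy()
        premise[0, 0, 2] += 0.15  # perturbed center
        model = dataclasses.replace(model, premise=premise)
        X = rng.uniform(0, 1, size=(30, 1))
        y = np.sin(3 * X[:, 0])
        model = anfis.lse_consequent(model, X, y)
        before = anfis.training_mse(model, X, y)
        after = anfis.training_mse(
            anfis.gd_premise_step(model, X, y, lr=1e-4), X, y
        )
        assert after <= before + 1e-12


class TestTrainHybrid:
    def test_zero_epochs_is_identity(self, toy_model, rng):
        X = rng.uniform(0, 1, size=(10, 2))
        model, trace = anfis.train_hybrid(toy_model, X, rng.normal(size=10), epochs=0)
        assert trace.size == 0
        np.testing.assert_array_equal(model.consequent, toy_model.consequent)
        np.testing.assert_array_equal(model.premise, toy_model.premise)

    def test_constant_target_fits_exactly(self, rng):
        model = anfis.build_model(2, AnfisConfig(n_mfs=2, epochs=5))
        X = rng.uniform(0, 1, size=(25, 2))
        _, trace = anfis.train_hybrid(model, X, np.full(25, 0.7))
        assert trace[-1] == pytest.approx(0.0, abs=1e-20)

    def test_recovers_generating_sugeno_system(self):
        data, _ = synthetic.generate_sugeno(2, 2, seed=11, n_samples=200)
        y = (data.y - data.y.min()) / (data.y.max() - data.y.min())
        model = anfis.build_model(2, AnfisConfig(n_mfs=2, epochs=40))
        _, trace = anfis.train_hybrid(model, data.X, y)
        assert np.sqrt(trace[-1]) < 0.05

    def test_trace_has_one_entry_per_epoch(self, rng):
        model = anfis.build_model(1, AnfisConfig(n_mfs=2, epochs=7))
        X = rng.uniform(0, 1, size=(12, 1))
        _, trace = anfis.train_hybrid(model, X, rng.normal(size=12))
        assert trace.shape == (7,)


class TestSerialization:
    def test_json_roundtrip_preserves_outputs_bitwise(self, rng):
        data, gen = synthetic.generate_sugeno(2, 2, seed=5, n_samples=10)
        back = anfis.AnfisModel.from_json(gen.to_json())
        assert np.array_equal(anfis.predict(back, data.X), anfis.predict(gen, data.X))
        assert back.config == gen.config
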