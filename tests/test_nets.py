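"""Channel models: losses, architecture contracts, SE gating, parameter
accounting, and gradient correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrrecg.nets import (
    ChannelModel,
    ModelConfig,
    SEBlock,
    build_model,
    class_weights,
    composite_loss,
    count_params,
    extract_features,
    iter_layers,
    tiny_config,
    weighted_bce,
    weighted_bce_grad,
)
from mrrecg.nets.layers import BatchNorm1d, Conv1d, Dense


class TestClassWeights:
    def test_high_precision_log_oracle(self):
        w = class_weights(np.array([3, 9501]))
        assert w.w[0] == pytest.approx(1 / math.log(3), rel=1e-12)
        assert w.w[0] == pytest.approx(0.9102, abs=5e-5)
        assert w.w[1] == pytest.approx(1 / math.log(9501), rel=1e-12)
        assert w.w[1] == pytest.approx(0.1092, abs=5e-5)

    def test_monotone_decreasing_in_count(self):
        w = class_weights(np.array([3, 9501]))
        assert w.w[0] > w.w[1]

    def test_count_below_two_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.array([1, 10]))


class TestWeightedBCE:
    def test_perfect_prediction_is_near_zero(self):
        loss = weighted_bce([1 - 1e-7, 1e-7], [1, 0], np.ones(2))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uninformative_prediction_is_ln2(self):
        loss = weighted_bce([0.5, 0.5], [1, 0], np.ones(2))
        assert loss == pytest.approx(math.log(2), rel=1e-12)

    def test_linear_in_weights(self):
        x, y = [0.8, 0.3], [1, 0]
        assert weighted_bce(x, y, 2 * np.ones(2)) == pytest.approx(
            2 * weighted_bce(x, y, np.ones(2))
        )

    def test_unit_weights_equal_standard_mean_bce(self, rng):
        for _ in range(50):
            x = rng.uniform(0.02, 0.98, size=(6, 5))
            y = (rng.random((6, 5)) < 0.4).astype(float)
            ours = weighted_bce(x, y, np.ones(5))
            standard = -np.mean(y * np.log(x) + (1 - y) * np.log(1 - x))
            assert ours == pytest.approx(standard, rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            weighted_bce([0.5, 0.5], [1, 0, 1], np.ones(2))

    def test_gradient_matches_finite_difference(self, rng):
        x = rng.uniform(0.1, 0.9, size=(3, 4))
        y = (rng.random((3, 4)) < 0.5).astype(float)
        w = rng.uniform(0.5, 2.0, size=4)
        g = weighted_bce_grad(x, y, w)
        eps = 1e-6
        for i, j in [(0, 0), (1, 2), (2, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            num = (weighted_bce(xp, y, w) - weighted_bce(xm, y, w)) / (2 * eps)
            assert g[i, j] == pytest.approx(num, rel=1e-5)


class TestCompositeLoss:
    def test_printed_coefficients(self):
        assert composite_loss(1.0, 1.0, 1.0) == pytest.approx(1.6)
        assert composite_loss(0.0, 0.0, 0.0) == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(main=st.floats(0, 10))
    def test_reduces_to_main_without_aux(self, main):
        assert composite_loss(main, 0.0, 0.0) == pytest.approx(main)


class TestBuildModel:
    @pytest.mark.parametrize("family", ["googlenet", "resnet", "se_inception",
                                        "se_resnet"])
    def test_forward_shape_and_sigmoid_range(self, family, rng):
        model = build_model(tiny_config(family, n_classes=3, seed=1), n_leads=8)
        x = rng.normal(size=(4, 8, 320))
        probs = model.forward(x, train=False)
        assert probs.shape == (4, 3)
        assert ((probs > 0) & (probs < 1)).all()

    def test_aux_heads_only_in_training_mode(self, rng):
        model = build_model(tiny_config("googlenet", 2, seed=1), n_leads=8)
        x = rng.normal(size=(2, 8, 320))
        probs, aux = model.forward(x, train=True)
        assert len(aux) == 1  # tiny profile has one tap
        assert all(a.shape == (2, 2) for a in aux)

    def test_length_agnostic_via_global_pooling(self, rng):
        model = build_model(tiny_config("resnet", 2, seed=0), n_leads=8)
        for n in (64, 300, 1000):
            out = model.forward(rng.normal(size=(1, 8, n)), train=False)
            assert out.shape == (1, 2)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelConfig(family="vgg", n_classes=2)


class TestSEGating:
    @pytest.mark.parametrize("variant", ["fc", "conv"])
    def test_each_channel_scaled_by_one_scalar_in_unit_interval(self, variant, rng):
        se = SEBlock(8, reduction=4, variant=variant, rng=rng)
        x = rng.normal(size=(3, 8, 20))
        y = se.forward(x)
        gates = se.gates(x)
        assert ((gates > 0) & (gates < 1)).all()
        np.testing.assert_allclose(y, x * gates[:, :, None], rtol=1e-12)


def independent_param_tally(model: ChannelModel) -> int:
    """Walk every layer's shape arithmetic instead of Parameter sizes."""
    total = 0
    seen = set()
    roots = list(model.path) + [h for h, _ in model.taps.values()]
    roots += [model.pool, model.dropout, model.fc, model.out]
    for layer in roots:
        for sub in iter_layers(layer):
            if id(sub) in seen:
                continue
            seen.add(id(sub))
            if isinstance(sub, Conv1d):
                total += sub.c_out * sub.c_in * sub.kernel
                if sub.bias is not None:
                    total += sub.c_out
            elif isinstance(sub, Dense):
                n_in, n_out = sub.weight.value.shape
                total += n_in * n_out + n_out
            elif isinstance(sub, BatchNorm1d):
                total += 2 * sub.gamma.value.shape[0]
    return total


class TestCountParams:
    def test_fc_se_block_example(self):
        # c=64, reduction 16: (64*4 + 4) + (4*64 + 64) = 580
        se = SEBlock(64, reduction=16, variant="fc")
        assert sum(p.size for p in se.params()) == 580

    def test_se_resnet_strictly_larger_than_resnet(self):
        base = tiny_config("resnet", 4, seed=0)
        se = tiny_config("se_resnet", 4, seed=0)
        assert count_params(build_model(se)) > count_params(build_model(base))

    @pytest.mark.parametrize("family", ["googlenet", "resnet", "se_resnet"])
    def test_matches_independent_shape_tally(self, family):
        model = build_model(tiny_config(family, 3, seed=2), n_leads=8)
        assert count_params(model) == independent_param_tally(model)


class TestFeatureExtraction:
    def test_untrained_model_refuses(self, rng):
        model = build_model(tiny_config("resnet", 2, seed=0))
        with pytest.raises(RuntimeError, match="trained"):
            extract_features(model, rng.normal(size=(2, 8, 128)))

    def test_eval_mode_deterministic_and_dimensioned(self, rng):
        model = build_model(tiny_config("resnet", 3, seed=0))
        model.trained = True  # behavioural contract only needs eval mode
        x = rng.normal(size=(4, 8, 256))
        a = extract_features(model, x)
        b = extract_features(model, x)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (4, model.feature_dim)
        assert model.feature_dim == 3  # logits source: one per class

    def test_pooled_source_dimension(self):
        from dataclasses import replace

        cfg = replace(tiny_config("resnet", 3, seed=0), feature_source="pooled")
        model = build_model(cfg)
        model.trained = True
        x = np.random.default_rng(0).normal(size=(2, 8, 256))
        assert extract_features(model, x).shape == (2, model.pooled_dim)


class TestGradients:
    @pytest.mark.parametrize("family", ["googlenet", "se_resnet"])
    def test_backprop_matches_finite_differences(self, family, rng):
        from dataclasses import replace

        cfg = replace(
            tiny_config(family, 3, seed=1), width=0.08, dropout=0.0
        )
        model = build_model(cfg, n_leads=2)
        x = rng.normal(size=(3, 2, 96))
        y = (rng.random((3, 3)) < 0.5).astype(float)
        w = np.array([1.0, 0.7, 1.3])

        def loss_value():
            probs, aux = model.forward(x, train=True)
            losses = [weighted_bce(probs, y, w)] + [
                weighted_bce(a, y, w) for a in aux
            ]
            if len(losses) == 3:
                return composite_loss(*losses)
            return losses[0] + 0.3 * sum(losses[1:])

        probs, aux = model.forward(x, train=True)
        for p in model.params():
            p.grad[...] = 0.0
        model.backward(
            weighted_bce_grad(probs, y, w),
            [0.3 * weighted_bce_grad(a, y, w) for a in aux],
        )
        params = model.params()
        for pi in rng.choice(len(params), size=5, replace=False):
            p = params[pi]
            flat = p.value.ravel()
            k = int(rng.integers(flat.size))
            eps = 1e-6
            orig = flat[k]
            flat[k] = orig + eps
            lp = loss_value()
            flat[k] = orig - eps
            lm = loss_value()
            flat[k] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[k]
            assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-6)
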