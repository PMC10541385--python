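"""Curve interpolation, augmentation, and the curve-correction network."""

import numpy as np
import pytest

import ctperf as c
from ctperf.cnn import CurvePair, first_pass_area, _mirror, _rotate
from ctperf.errors import ConfigError, InputError, StateError
from ctperf.training import sample_aif


def gamma_curve(n=90):
    t = np.arange(float(n))
    return c.gamma_variate(t, c.GammaParams(K=2.0, AT=5.0, alpha=3.0, beta=1.5))


class TestInterpolateCurve:
    def test_output_length_500(self):
        out = c.interpolate_curve(gamma_curve(), 500)
        assert len(out) == 500

    def test_linear_ramp_preserved(self):
        t = np.arange(20.0)
        out = c.interpolate_curve(c.ConcentrationCurve(t, 3.0 * t + 1.0), 200)
        np.testing.assert_allclose(out.values, 3.0 * out.times + 1.0, atol=1e-9)

    def test_endpoints_exact(self):
        curve = gamma_curve()
        out = c.interpolate_curve(curve, 333)
        assert out.values[0] == curve.values[0]
        assert out.values[-1] == curve.values[-1]
        assert out.times[0] == curve.times[0] and out.times[-1] == curve.times[-1]

    def test_too_few_samples_rejected(self):
        t = np.arange(3.0)
        with pytest.raises(InputError):
            c.interpolate_curve(c.ConcentrationCurve(t, t), 100)


class TestAugmentation:
    def _pairs(self, n_pairs):
        rng = np.random.default_rng(0)
        base = c.interpolate_curve(gamma_curve(), 120)
        base_v = np.clip(base.values, 0.0, None)
        out = []
        for _ in range(n_pairs):
            v = base_v * rng.uniform(0.5, 1.5)
            out.append(
                CurvePair(
                    input_values=v,
                    label_values=v / v.sum(),
                    times=base.times,
                )
            )
        return out

    def test_three_per_source_384_to_1152(self):
        pairs = self._pairs(384)
        assert len(c.augment_pairs(pairs, seed=0)) == 1152

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            c.augment_pairs([], seed=0)

    def test_mirror_is_involution_for_central_peak(self):
        n = 101
        x = np.linspace(-1, 1, n)
        v = np.exp(-(x**2) / 0.1)  # peak at the center sample
        pivot = int(np.argmax(v))
        np.testing.assert_allclose(_mirror(_mirror(v, pivot), pivot), v)

    def test_rotation_zero_angle_identity(self):
        v = gamma_curve().values
        np.testing.assert_allclose(_rotate(v, 0.0), np.clip(v, 0, None), atol=1e-9)

    def test_label_and_input_transformed_consistently(self):
        # a pair whose label equals its input must stay degenerate
        # (up to label renormalization) after augmentation
        base = c.interpolate_curve(gamma_curve(), 120)
        v = np.clip(base.values, 0.0, None)
        pair = CurvePair(input_values=v, label_values=v, times=base.times)
        for aug in c.augment_pairs([pair], seed=1):
            np.testing.assert_allclose(
                np.clip(aug.input_values, 0, None), aug.label_values, atol=1e-9
            )


class TestModel:
    def test_output_layer_width_matches_input_length(self):
        model = c.build_model(c.CNNConfig(input_length=500))
        q = model.forward(np.zeros((2, 500)))
        assert q.shape == (2, 500)

    def test_softmax_sums_to_one(self):
        model = c.build_model(c.CNNConfig(input_length=64))
        rng = np.random.default_rng(0)
        q = model.forward(rng.normal(size=(5, 64)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(q >= 0)

    def test_seeded_builds_identical(self):
        cfg = c.CNNConfig(input_length=64, seed=7)
        m1, m2 = c.build_model(cfg), c.build_model(cfg)
        assert m1.n_parameters == m2.n_parameters
        x = np.random.default_rng(1).normal(size=(4, 64))
        y = np.abs(x)
        y /= y.sum(axis=1, keepdims=True)
        assert m1.loss(x, y) == m2.loss(x, y)

    def test_pool_larger_than_sequence_rejected(self):
        with pytest.raises(ConfigError):
            c.CNNConfig(input_length=4, pool=8)

    def test_gradient_matches_finite_differences(self):
        # numerical check of the hand-written backward pass; biases are
        # shifted so every ReLU is active (the loss is locally smooth,
        # otherwise finite differences straddle kinks)
        cfg = c.CNNConfig(input_length=12, conv_filters=(2, 3), dense_units=4, seed=0)
        model = c.build_model(cfg)
        for b in ("bc0", "bc1", "bd0"):
            model.params[b] += 5.0
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 12))
        y = np.abs(rng.normal(size=(3, 12)))
        y /= y.sum(axis=1, keepdims=True)
        _, caches = model.forward(x, cache=True)
        grads = model._backward(caches, y)
        eps = 1e-6
        for name in ("Wc0", "Wd0", "Wd1", "bc1", "bd0"):
            p = model.params[name]
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            lp = model.loss(x, y)
            p[idx] -= 2 * eps
            lm = model.loss(x, y)
            p[idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_loss_decreases(self, trained_model):
        hist = trained_model.history
        assert hist[-1] < hist[0]

    def test_single_batch_overfits(self):
        cfg = c.CNNConfig(input_length=100, epochs=300, batch_size=32, seed=1)
        rng = np.random.default_rng(2)
        t = np.linspace(0, 89, 100)
        pairs = []
        for _ in range(32):
            g = c.gamma_variate(
                t, c.GammaParams(rng.uniform(1, 2), rng.uniform(2, 8), 3.0, 1.5)
            )
            y = g.values / g.values.sum()
            x = g.values / g.values.max() + rng.normal(0, 0.05, 100)
            pairs.append(CurvePair(input_values=x, label_values=y, times=t))
        model = c.build_model(cfg)
        _, hist = c.train_model(model, pairs)
        # cross-entropy is bounded below by the label entropy; training
        # should approach that floor on a memorized batch
        ys = np.stack([p.label_values for p in pairs])
        entropy = float(-(ys * np.log(ys + 1e-12)).sum(axis=1).mean())
        assert hist[-1] - entropy < 0.05

    def test_too_few_pairs_rejected(self):
        model = c.build_model(c.CNNConfig(input_length=32, batch_size=32))
        t = np.arange(32.0)
        pair = CurvePair(np.ones(32), np.ones(32) / 32, t)
        with pytest.raises(InputError):
            c.train_model(model, [pair] * 8)


class TestPredictAIF:
    def test_untrained_model_rejected(self):
        model = c.build_model(c.CNNConfig())
        with pytest.raises(StateError):
            c.predict_aif(model, gamma_curve())

    def test_output_nonnegative_on_native_grid(self, trained_model):
        _, distorted = sample_aif(np.random.default_rng(77))
        out = c.predict_aif(trained_model, distorted)
        assert np.all(out.values >= 0)
        assert len(out) == len(distorted)
        np.testing.assert_array_equal(out.times, distorted.times)

    def test_clean_curve_maps_near_its_own_gamma_fit(self, trained_model):
        clean, _ = sample_aif(np.random.default_rng(101))
        pred = c.predict_aif(trained_model, clean)
        params, _ = c.fit_gamma(clean)
        fit = c.gamma_variate(clean.times, params)
        rmse = np.sqrt(((pred.values - fit.values) ** 2).mean())
        assert rmse < 0.10 * fit.values.max()

    def test_baseline_drift_removed(self, trained_model):
        # distorted curve in -> predicted pre-arrival baseline < 5% of peak
        rng = np.random.default_rng(55)
        fracs = []
        for _ in range(20):
            _, distorted = sample_aif(rng)
            pred = c.predict_aif(trained_model, distorted)
            peak = pred.values.max()
            j0 = np.nonzero(pred.values > 0.1 * peak)[0][0]
            base = pred.values[: max(j0, 1)].mean()
            fracs.append(base / peak)
        assert np.median(fracs) < 0.05

    def test_save_load_roundtrip(self, trained_model, tmp_path):
        path = tmp_path / "model.npz"
        c.save_model(trained_model, path)
        loaded = c.load_model(path)
        x = np.random.default_rng(3).normal(size=(2, trained_model.config.input_length))
        np.testing.assert_array_equal(trained_model.forward(x), loaded.forward(x))
        assert loaded.trained


class TestFirstPassArea:
    def test_matches_trapezoid_on_pure_gamma(self):
        curve = gamma_curve()
        area = first_pass_area(curve)
        full = np.trapezoid(curve.values, curve.times)
        assert area == pytest.approx(full, rel=0.02)
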