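"""Digital phantom generation, AIF distortion and synthetic scores."""

import dataclasses

import numpy as np
import pytest

import ctperf as c
from ctperf.errors import ConfigError, InputError
from ctperf.phantom import clean_aif


class TestGeneratePhantom:
    def test_seeded_reproducibility(self):
        s1, t1 = c.generate_phantom(seed=5)
        s2, t2 = c.generate_phantom(seed=5)
        assert np.array_equal(s1.volume, s2.volume)
        assert np.array_equal(t1.core_mask_true, t2.core_mask_true)

    def test_different_seeds_differ(self):
        s1, _ = c.generate_phantom(seed=5)
        s2, _ = c.generate_phantom(seed=6)
        assert not np.array_equal(s1.volume, s2.volume)

    def test_exact_volume_bookkeeping_at_1mm3(self):
        cfg = dataclasses.replace(
            c.PhantomConfig(),
            shape=(48, 48, 30),
            spacing=(1.0, 1.0, 1.0),
            core_volume_ml=10.0,
            penumbra_volume_ml=20.0,
            noise_snr=None,
        )
        _, truth = c.generate_phantom(cfg, seed=0)
        assert truth.core_mask_true.sum() == 10_000
        assert truth.penumbra_mask_true.sum() == 20_000

    def test_mask_nesting_and_containment(self, noisy_phantom):
        _, study, truth = noisy_phantom
        assert not np.any(truth.core_mask_true & ~truth.penumbra_mask_true)
        assert not np.any(truth.penumbra_mask_true & ~study.brain_mask)
        assert not np.any(study.artery_mask & ~study.brain_mask)
        assert np.all(truth.cbf_true >= 0)

    def test_lesion_outside_brain_rejected(self):
        cfg = dataclasses.replace(c.PhantomConfig(), lesion_center=(0, 0, 0))
        with pytest.raises(ConfigError):
            c.generate_phantom(cfg, seed=0)

    def test_lesion_larger_than_brain_rejected(self):
        cfg = dataclasses.replace(
            c.PhantomConfig(), penumbra_volume_ml=10_000.0, core_volume_ml=10.0
        )
        with pytest.raises(ConfigError):
            c.generate_phantom(cfg, seed=0)

    def test_forward_inverse_consistency_single_voxel(self, clean_phantom):
        # deconvolving a noiseless tissue voxel with the clean AIF
        # recovers the generating CBF within 5%
        _, study, truth = clean_phantom
        reg = c.DeconvConfig(truncation=0.002)
        for mask, cbf in (
            (truth.penumbra_mask_true & ~truth.core_mask_true, 25.0),
            (truth.core_mask_true, 8.0),
        ):
            i, j, k = np.argwhere(mask)[0]
            ct = c.ConcentrationCurve(study.times, study.volume[i, j, k])
            r = c.deconvolve(ct, truth.aif_clean, reg)
            assert c.compute_cbf(r) == pytest.approx(cbf, rel=0.05)

    def test_artery_carries_clean_aif_when_undistorted(self, clean_phantom):
        _, study, truth = clean_phantom
        i, j, k = np.argwhere(study.artery_mask)[0]
        assert np.allclose(study.volume[i, j, k], truth.aif_clean.values)


class TestDistortAIF:
    @pytest.fixture()
    def aif(self):
        return clean_aif(c.PhantomConfig())

    def test_zero_strength_is_identity(self, aif):
        out = c.distort_aif(aif, c.DistortionParams(), seed=3)
        assert np.array_equal(out.values, aif.values)

    def test_baseline_slope_on_prearrival_samples(self, aif):
        d = c.DistortionParams(baseline_slope=0.1)
        out = c.distort_aif(aif, d, seed=0)
        pre = aif.times < 4.0  # before bolus arrival at 5 s
        np.testing.assert_allclose(
            out.values[pre] - aif.values[pre], 0.1 * aif.times[pre], atol=1e-9
        )

    def test_peak_attenuation_halves_the_peak(self, aif):
        d = c.DistortionParams(peak_attenuation=0.5)
        out = c.distort_aif(aif, d, seed=0)
        assert out.values.max() == pytest.approx(0.5 * aif.values.max(), rel=1e-6)

    def test_output_nonnegative(self, aif):
        d = c.DistortionParams(
            baseline_slope=0.0, baseline_noise_sd=1.0, peak_attenuation=0.5
        )
        out = c.distort_aif(aif, d, seed=9)
        assert np.all(out.values >= 0)

    def test_recirc_rescaled_to_requested_fraction(self, aif):
        d = c.DistortionParams(recirc_amplitude=0.05)
        out = c.distort_aif(aif, d, seed=0)
        peak_j = int(np.argmax(out.values))
        trough = peak_j + int(np.argmin(out.values[peak_j : peak_j + 20]))
        recirc_peak = out.values[trough + 1 :].max()
        assert recirc_peak == pytest.approx(0.05 * out.values.max(), rel=1e-6)

    def test_attenuation_monotonically_reduces_rmse(self, aif):
        # fixed seed: distorted curves approach the clean one as the
        # first-pass attenuation approaches 1
        rmses = []
        for atten in (0.5, 0.7, 0.9, 1.0):
            d = c.DistortionParams(peak_attenuation=atten)
            out = c.distort_aif(aif, d, seed=4)
            rmses.append(np.sqrt(((out.values - aif.values) ** 2).mean()))
        assert all(a >= b for a, b in zip(rmses, rmses[1:]))
        assert rmses[-1] == 0.0


class TestClinicalScores:
    def test_monotone_in_penumbra_volume(self):
        cfg_small = dataclasses.replace(
            c.PhantomConfig(), penumbra_volume_ml=50.0, core_volume_ml=5.0
        )
        cfg_large = dataclasses.replace(
            c.PhantomConfig(), penumbra_volume_ml=150.0, core_volume_ml=5.0
        )
        _, t_small = c.generate_phantom(cfg_small, seed=0)
        _, t_large = c.generate_phantom(cfg_large, seed=0)
        s_small = c.synth_clinical_scores(t_small, noise_sd=0.0, seed=0)
        s_large = c.synth_clinical_scores(t_large, noise_sd=0.0, seed=0)
        assert s_small.nihss <= s_large.nihss

    def test_aspects_ceiling_with_no_core(self):
        cfg = dataclasses.replace(
            c.PhantomConfig(), core_volume_ml=0.0, penumbra_volume_ml=40.0
        )
        _, truth = c.generate_phantom(cfg, seed=0)
        scores = c.synth_clinical_scores(truth, noise_sd=0.0, seed=0, b=5.0)
        assert scores.aspects == 10

    def test_scores_within_scale_bounds(self):
        cfg = dataclasses.replace(
            c.PhantomConfig(), penumbra_volume_ml=180.0, core_volume_ml=70.0
        )
        _, truth = c.generate_phantom(cfg, seed=0)
        s = c.synth_clinical_scores(truth, noise_sd=50.0, seed=1)
        assert 0 <= s.nihss <= 42 and 0 <= s.aspects <= 10
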