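"""Deconvolution, CBF/Tmax extraction, and voxelwise map computation."""

import dataclasses

import numpy as np
import pytest

import ctperf as c
from ctperf.errors import InputError

DT = 1.0
NOISELESS = c.DeconvConfig(truncation=0.002)


def gamma_aif(n=90, K=2.0, AT=5.0):
    t = np.arange(n) * DT
    return c.gamma_variate(t, c.GammaParams(K=K, AT=AT, alpha=3.0, beta=1.5))


def forward(ca, residue):
    ct = DT * np.convolve(ca.values, residue)[: len(ca)]
    return c.ConcentrationCurve(ca.times, ct)


class TestDeconvolve:
    def test_zero_tissue_curve_gives_zero_residue(self):
        ca = gamma_aif()
        ct = c.ConcentrationCurve(ca.times, np.zeros(len(ca)))
        r = c.deconvolve(ct, ca)
        assert np.allclose(r.values, 0.0)

    def test_boxcar_residue_height_recovered(self):
        ca = gamma_aif()
        t = ca.times
        F = 0.01
        residue = F * ((t >= 2.0) & (t < 6.0)).astype(float)
        r = c.deconvolve(forward(ca, residue), ca, NOISELESS)
        assert r.values.max() == pytest.approx(F, rel=0.05)

    def test_delay_shifts_argmax(self):
        ca = gamma_aif()
        t = ca.times
        F = 0.01
        base = F * ((t >= 1.0) & (t < 5.0)).astype(float)
        delayed = F * ((t >= 5.0) & (t < 9.0)).astype(float)
        r0 = c.deconvolve(forward(ca, base), ca, NOISELESS)
        r4 = c.deconvolve(forward(ca, delayed), ca, NOISELESS)
        t0 = c.compute_tmax(r0, tie_tol=0.02)
        t4 = c.compute_tmax(r4, tie_tol=0.02)
        assert t4 - t0 == pytest.approx(4.0, abs=DT)

    def test_zero_area_aif_rejected(self):
        t = np.arange(16.0)
        flat = c.ConcentrationCurve(t, np.zeros(16))
        with pytest.raises(InputError):
            c.deconvolve(flat, flat)

    def test_grid_mismatch_rejected(self):
        ca = gamma_aif(90)
        ct = c.ConcentrationCurve(np.arange(60.0), np.ones(60))
        with pytest.raises(InputError):
            c.deconvolve(ct, ca)

    @pytest.mark.parametrize("n", [8, 12, 16])
    def test_fft_matches_explicit_svd_oracle(self, n):
        # spectral inverse of the circulant operator == truncated SVD of
        # the explicit convolution matrix
        rng = np.random.default_rng(n)
        t = np.arange(float(n))
        ca = c.ConcentrationCurve(t, np.clip(rng.normal(1.0, 0.5, n), 0.01, None))
        ct = c.ConcentrationCurve(t, rng.normal(0.0, 1.0, n))
        for trunc in (0.0, 0.15, 0.4):
            reg = c.DeconvConfig(truncation=trunc)
            r_fft = c.deconvolve(ct, ca, reg)
            r_svd = c.deconvolve_matrix(ct, ca, reg)
            np.testing.assert_allclose(r_fft.values, r_svd.values, atol=1e-6)


class TestScalars:
    def test_cbf_of_zero_residue(self):
        r = c.ResidueFunction(np.arange(10.0), np.zeros(10))
        assert c.compute_cbf(r) == 0.0

    def test_cbf_linear_in_residue(self):
        t = np.arange(10.0)
        v = np.exp(-t / 3.0)
        r1 = c.ResidueFunction(t, v)
        r2 = c.ResidueFunction(t, 2 * v)
        assert c.compute_cbf(r2) == pytest.approx(2 * c.compute_cbf(r1))

    def test_cbf_unit_scale(self):
        r = c.ResidueFunction(np.arange(5.0), np.array([0.0, 0.01, 0.005, 0.0, 0.0]))
        assert c.compute_cbf(r, scale=6000.0) == pytest.approx(60.0)

    def test_tmax_unique_maximum(self):
        t = np.arange(10.0)
        v = np.zeros(10)
        v[6] = 1.0
        assert c.compute_tmax(c.ResidueFunction(t, v)) == 6.0

    def test_tmax_constant_residue_breaks_tie_earliest(self):
        t = np.arange(10.0)
        assert c.compute_tmax(c.ResidueFunction(t, np.ones(10))) == 0.0


class TestComputeMaps:
    def test_all_zero_study_gives_zero_maps(self):
        shape = (8, 8, 2)
        n = 20
        t = np.arange(float(n))
        brain = np.ones(shape, dtype=bool)
        artery = np.zeros(shape, dtype=bool)
        artery[0, 0, 0] = True
        study = c.CTPStudy(
            volume=np.zeros(shape + (n,)),
            times=t,
            spacing=(1, 1, 1),
            brain_mask=brain,
            artery_mask=artery,
        )
        aif = c.gamma_variate(t, c.GammaParams(1.0, 2.0, 2.0, 1.0))
        maps = c.compute_maps(study, aif)
        assert np.all(maps.cbf == 0) and np.all(maps.tmax == 0)

    def test_deterministic(self, noisy_phantom):
        _, study, truth = noisy_phantom
        m1 = c.compute_maps(study, truth.aif_clean)
        m2 = c.compute_maps(study, truth.aif_clean)
        assert np.array_equal(m1.cbf, m2.cbf) and np.array_equal(m1.tmax, m2.tmax)

    def test_grid_mismatch_rejected(self, noisy_phantom):
        _, study, truth = noisy_phantom
        bad = c.ConcentrationCurve(
            truth.aif_clean.times[:-1], truth.aif_clean.values[:-1]
        )
        with pytest.raises(InputError):
            c.compute_maps(study, bad)

    def test_noiseless_phantom_recovery(self, clean_phantom):
        # median relative CBF error over lesioned voxels < 10% with the
        # clean AIF and noise-matched (near-zero) regularization
        _, study, truth = clean_phantom
        maps = c.compute_maps(study, truth.aif_clean, reg=NOISELESS)
        lesion = truth.penumbra_mask_true
        rel = np.abs(maps.cbf[lesion] - truth.cbf_true[lesion]) / truth.cbf_true[lesion]
        assert np.median(rel) < 0.10

    def test_noiseless_delay_recovery_within_one_step(self, clean_phantom):
        _, study, truth = clean_phantom
        maps = c.compute_maps(study, truth.aif_clean, reg=NOISELESS)
        core = truth.core_mask_true
        med_tmax = np.median(maps.tmax[core])
        assert abs(med_tmax - 10.0) <= 1.0  # core delay 10 s

    def test_tmax_bounded_by_duration(self, noisy_phantom):
        _, study, truth = noisy_phantom
        maps = c.compute_maps(study, truth.aif_clean)
        assert maps.tmax.min() >= 0
        assert maps.tmax.max() <= study.times[-1]


class TestDistortionDegradesRecovery:
    def test_cbf_overestimation_monotone_in_peak_attenuation(self):
        # the premise of AIF correction: a shallower measured first pass
        # inflates the recovered CBF, monotonically in the attenuation
        # (dividing the tissue curve by a smaller kernel)
        ca = gamma_aif()
        t = ca.times
        F = 60.0 / 6000.0
        residue = F * np.where(t >= 1.0, np.exp(-np.clip(t - 1.0, 0, None) / 4.0), 0.0)
        ct = forward(ca, residue)
        cbfs = []
        for atten in (1.0, 0.8, 0.6, 0.4):
            d = c.DistortionParams(peak_attenuation=atten)
            ca_d = c.distort_aif(ca, d, seed=0)
            r = c.deconvolve(ct, ca_d, c.DeconvConfig(truncation=0.05))
            cbfs.append(c.compute_cbf(r))
        assert all(a <= b + 1e-9 for a, b in zip(cbfs, cbfs[1:]))
        assert cbfs[-1] > 1.5 * cbfs[0]
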