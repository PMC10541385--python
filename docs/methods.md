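# Methods

This note documents the models, numerical choices and limitations behind
`ctperf`. It is the package's own account; every number quoted here is computed
by the test suite or by `scripts/acceptance.py`.

## Perfusion model and deconvolution

Each tissue voxel's contrast concentration is modeled as the convolution of the
arterial input C_a with a flow-scaled, delayed residue function:

    C_t(t) = Δt · (C_a ⊛ R)(t),   R(t) = CBF · r(t − delay),

with r either exponential, r(t) = exp(−t/MTT), or a boxcar of width MTT.
Deconvolution uses the block-circulant formulation: both curves are zero-padded
to twice the acquisition length, the circulant kernel matrix is diagonalized by
the FFT, and singular values below `truncation × σ_max` are discarded. Because
the operator is circulant, the spectral implementation and an explicit
truncated-SVD solve of the dense convolution matrix are the same map; the test
suite checks agreement to 1e-6 on small problems and the two paths are kept as
separate code (FFT for production, dense SVD as an oracle).

Perfusion parameters follow the standard definitions: CBF = scale · max R(t)
with `scale = 6000` converting 1/s to mL/100 g/min (the 100 g and per-minute
factors, 100·60), and Tmax = argmax R(t) with ties broken to the earliest
sample. Tie detection uses a relative tolerance (default 1e-9, i.e. exact
plateaus only); tests that recover boxcar delays widen it to 2% because
regularized deconvolution leaves small ripples along a plateau.

**Truncation threshold.** The default is 0.15·σ_max, a standard operating point
for noisy clinical data. Truncation is a noise regularizer, and it is *biased*:
on noiseless curves it suppresses the residue peak by tens of percent. Noiseless
validation therefore uses `truncation = 0.002`, which recovers CBF within ~4%
and delays within one frame across exponential and boxcar residues. Matching the
regularization strength to the noise level is the user's responsibility, as in
any cSVD implementation.

**Baseline handling.** Bolus arrival is the first frame where the AIF exceeds
10% of its peak; the mean of earlier frames is subtracted per voxel (and from
the AIF) before deconvolution. Non-uniform time stamps are linearly resampled to
the median interval.

## Gamma-variate model and fitting

The arterial first passage is K(t−AT)^α exp(−(t−AT)/β) for t > AT, zero before
arrival. Fitting is bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, xtol 1e-8, at most 500 residual evaluations)
with a moment-based initial guess: AT from the 10%-of-peak crossing, α·β from
the peak time, and K from the peak value. The default fit window runs from the
first sample to the first local minimum after the global peak, excluding
recirculation, which the first-passage model does not describe.

Noiseless curves are recovered to ~1e-9 relative error across a wide parameter
grid. Under noise, the *identifiable* quantities — arrival time, peak time,
peak value, and the fitted curve itself — recover within a few percent (median,
SNR 20), but raw K and α individually do not: they trade off along a flat
likelihood valley while the curve barely changes. This is an intrinsic property
of the parameterization, not of the optimizer, and the tests assert recovery of
the identifiable quantities.

## The curve-correction network

Architecture: input of 500 samples → conv(kernel 2, 8 filters, ReLU) →
conv(kernel 2, 16 filters, ReLU) → average pool (2) → flatten → dense(36, ReLU)
→ dense(500) with softmax. The softmax output is read as a *normalized curve
shape* (it sums to one); labels are gamma-variate fits normalized to unit sum,
and the loss is cross-entropy computed via log-softmax (exactly consistent with
the analytic gradient — the backward pass is verified against finite
differences). Training uses RMSprop (ρ = 0.9, ε = 1e-7), learning rate 0.001,
batch size 32; weights are Glorot-uniform from a seed, so builds and training
runs are reproducible. The filter widths (8, 16) and pool size are package
defaults — the parameter count (162,256) is not a target of any kind.

At inference the input curve is cubic-spline interpolated to the 500-sample
grid and peak-normalized; the predicted shape is rescaled so its integral
equals the measured curve's baseline-corrected first-pass area, then mapped
back to the native time grid. The output is therefore a nonnegative,
physically-scaled, gamma-like AIF regardless of how distorted the input was.

**Training data.** 128 simulated datasets each contribute 3 AIFs: a randomized
gamma bolus (K 1.5–2.5, arrival 3–8 s, α 2.5–3.5, β 1.2–1.8 s) with a 15–25%
recirculation 18–25 s later, passed through a randomized measurement distortion
(drift up to 0.05 a.u./s, additive noise SD 0.05–0.3, first-pass attenuation
down to 0.5, recirculation rescaling and ±3 s jitter). Labels are gamma fits of
the distorted curves — exactly how clustering-selected AIFs from real data
would be curve-fitted to build supervision. Augmentation (mirror about the
peak, ±5° polyline rotation, both) triples 384 source pairs to 1152; the
unaugmented originals are excluded by default but can be appended with a flag.
Held-out evaluation uses fresh distortion seeds; the trained network beats the
raw distorted input in RMSE-to-label on ≳95% of held-out curves and leaves a
pre-arrival baseline below ~2% of peak.

Training for the shipped experiments uses 50 epochs; the loss plateau is
reached well before the 300-epoch default, and the held-out win rate is the
quantity that matters, not the final loss.

## AIF selection

Within a supplied ROI (for phantoms, a small dilation of the true arterial
block — automatic vessel localization from anatomy is out of scope), voxels
with a temporal peak below 20% of the ROI maximum are discarded; remaining
curves are normalized to unit area and k-means clustered (k = 5, seeded); each
round keeps the cluster with the lowest mean first moment (tie-break: lowest
curve roughness, the sum of squared second differences) and recurses until ≤10
voxels, 5 rounds, or no further shrinkage. The final candidates are the
highest-peak voxels of the surviving set, 3 per dataset by default.

## Lesion segmentation

Core: CBF < f · reference for f ∈ {20, 30, 38}%, primary 30%. Penumbra:
Tmax > τ for τ ∈ {4, 6, 8, 10} s, primary 6 s. Strict inequalities, masks
restricted to the brain, volumes = voxel count × voxel volume. Nesting across
each threshold family holds by construction. No morphological cleanup is
applied by default.

The "relative CBF" reference is the median CBF of the hemisphere contralateral
to the lesion (operationally: the hemisphere with the higher median), restricted
to voxels with Tmax at or below the primary penumbra threshold, *excluding
vessels* (voxels whose temporal peak exceeds 3× the median brain peak —
deconvolving near-arterial voxels against the AIF yields spuriously enormous
CBF that would otherwise dominate the median). If no normally-perfused voxels
remain, the whole-brain non-vessel median is used and a warning logged.

## The digital phantom

A 64×64×4 slab of 2×2×5 mm voxels, 90 frames at 1 s. The brain is an
elliptical cylinder (~210 mL); the lesion is a spherical-metric region grown
voxel-by-voxel from a center in one hemisphere to an *exact* target volume
(default 60 mL penumbra containing a 10 mL core), so volumetric bookkeeping is
exact by construction. Tissue classes: healthy (CBF 60 mL/100 g/min, MTT 4 s,
delay 1 s), penumbra (25/8/8), core (8/12/10) — typical stroke-imaging values;
the core sits below 30% of healthy flow and both lesion classes above the 6 s
Tmax threshold. The clean AIF is a gamma bolus (K 2, AT 5 s, α 3, β 1.5 s) plus
a 20%-amplitude dispersed recirculation 20 s later. A 2×2×1 arterial block
carries the measured AIF — clean or distorted. Additive Gaussian noise with SD
= (healthy tissue peak)/SNR, default SNR 10, emulates CT noise after the
spatial smoothing every clinical pipeline applies.

The 90 s duration matters: block-circulant deconvolution assumes curves near
baseline by the end of acquisition, and with recirculation plus slow core
washout a 60 s window leaves large wrap-around artifacts even noiselessly.

**Distortion presets.** `SEVERE_DISTORTION` (drift 0.05 a.u./s, noise SD 0.3,
first-pass halved, recirculation rescaled to 5% of peak and jittered ±3 s)
makes the raw-AIF branch classify essentially the whole brain as penumbra — the
deconvolution must explain the tissue's recirculation energy with late residue
mass, which saturates Tmax. `OCCULT_CORE_DISTORTION` (first pass quartered,
noise SD 0.4, no drift), combined with a low-dose acquisition (SNR 5), raises
the deconvolution noise floor until the core/healthy CBF contrast disappears
and the reported core collapses to 0.0 mL on some seeds while the true core is
10 mL; the corrected branch keeps a nonzero core. Both presets were chosen by
forward reasoning about the truncated-SVD noise floor and frozen before being
wired into the validation.

**Synthetic severity scores.** NIHSS = clamp(round(0.15 · penumbra mL), 0, 42)
and ASPECTS = clamp(10 − round(0.35 · core mL), 0, 10), optionally with
Gaussian rater noise. These are monotone surrogates for cohort-level
correlation checks, nothing more: with the default slopes a 123 mL penumbra
maps to NIHSS ≈ 18 and a 10 mL core to ASPECTS ≈ 6–7.

**What the phantom does not model** — and hence what passing tests do not
show about real data: no anatomy (skull, gray/white matter, partial volume),
no beam hardening or dose modulation, spatially uncorrelated noise, piecewise-
constant perfusion classes with a single global AIF, and no motion. The rescue
experiments demonstrate the *mechanism* by which AIF correction repairs
thresholded volumes, not clinical accuracy.

## Validation statistics

Spearman's tie-corrected rank correlation (t-approximation p-values),
Bland–Altman mean difference with ±1.96·SD(n−1) limits of agreement, and the
two-sided Wilcoxon signed-rank test (zero differences dropped; exact null for
≤25 untied nonzero differences, tie-corrected normal approximation with
continuity correction otherwise). Spearman and Wilcoxon delegate to
scipy.stats behind this module's interface; the tests pin their behavior to
brute-force oracles (rank-Pearson to 1e-12; exact sign-pattern enumeration of
the Wilcoxon null; a Monte-Carlo type-I error of 0.05 ± 0.02 at n = 20 over
1000 replicates).

## Reproducibility

Every stochastic stage takes an explicit seed (phantom noise, distortions,
k-means, weight initialization, batch shuffling); identical seeds give
bit-identical phantoms and training runs on the same hardware/precision.
Pipeline outputs carry JSON sidecars with the configuration hash and seed.
`scripts/acceptance.py --seed N --out results/acceptance.json` re-runs the full
experiment chain (a few minutes on one CPU) and writes every measured quantity
with the problem size it was measured at.
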