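# ctperf

CT-perfusion (CTP) analysis for acute stroke with a learned arterial-input-function
(AIF) correction.

## The problem

Triage decisions in acute ischemic stroke rest on two volumes estimated from dynamic
contrast-enhanced CT: the irreversibly infarcted **core** (relative CBF < 30% of a
normal-tissue reference) and the salvageable, hypoperfused **penumbra** (Tmax > 6 s).
Both come from deconvolving each voxel's concentration time curve C_t(t) with the
arterial input function C_a(t),

    C_t(t) = (C_a ⊗ R)(t),     CBF = 100·60 · max_t R(t),     Tmax = argmax_t R(t),

where R(t) is the flow-scaled residue function. The AIF is measured from a handful of
arterial voxels and is routinely corrupted: a drifting or noisy baseline, a shallow
first-pass peak (partial volume), and an inconsistent recirculation portion. A distorted
kernel propagates through the deconvolution into wrong CBF/Tmax maps — in the worst case
the core is reported as 0 mL in a patient with a severe stroke.

`ctperf` addresses this by fitting the AIF's first passage to the gamma-variate bolus
model

    C(t) = K (t − AT)^α exp(−(t − AT)/β)    for t > AT, else 0

not by direct curve fitting at inference time, but through a small 1-D convolutional
network trained to map a distorted, spline-interpolated AIF (500 samples) to its
gamma-variate fit. The corrected "CNN AIF" then drives a delay-insensitive
block-circulant truncated-SVD deconvolution, thresholding, and volumetry. Everything is
validated end-to-end on a seeded digital perfusion phantom with known ground truth, plus
synthetic NIHSS/ASPECTS severity scores for cohort-level statistics (Spearman
correlation, Bland–Altman agreement, Wilcoxon signed-rank comparison).

The network (two kernel-2 convolutions with ReLU, average pooling, a 36-unit dense
layer, and a softmax output read as a normalized curve shape) is implemented directly in
numpy, including backpropagation and the RMSprop optimizer — it is small enough that a
full training run takes well under a minute on one CPU core.

## Worked example

Train the curve-correction network on a synthetic bank of 1152 distorted/gamma-fitted
curve pairs (128 simulated datasets × 3 AIFs × 3 augmentations), then analyze one
phantom with a severely distorted measured AIF, with and without the correction:

```bash
ctperf train-aif --out model.npz --n-datasets 128 --epochs 50 --seed 0
ctperf run-all --seed 0 --out run0 --model model.npz --severe-distortion
```

which prints:

```
training on 1152 pairs (162256 parameters)...
final loss 4.5122 (from 5.2390); saved to model.npz
with_cnn_aif: CBF < 20%=3.2 mL, CBF < 30%=9.0 mL, CBF < 38%=10.7 mL, Tmax > 4 s=60.2 mL, Tmax > 6 s=60.2 mL, Tmax > 8 s=59.8 mL, Tmax > 10 s=29.8 mL
without_cnn_aif: CBF < 20%=0.8 mL, CBF < 30%=5.9 mL, CBF < 38%=9.2 mL, Tmax > 4 s=210.3 mL, Tmax > 6 s=210.2 mL, Tmax > 8 s=210.2 mL, Tmax > 10 s=210.2 mL
```

The phantom's ground truth is a 10 mL core inside a 60 mL penumbra. With the corrected
AIF the pipeline reports a 9.0 mL core and a 60.2 mL penumbra. With the raw distorted
AIF the Tmax map saturates — the entire 210 mL brain is classified as penumbra, the
hemispheric reference collapses, and the core volume is unreliable. This is the failure
mode the correction exists to repair: across seeded phantoms, the median absolute
core-volume error drops several-fold when the CNN AIF replaces the raw curve, and
constructed low-dose cases where the raw branch reports core = 0 mL despite a true
infarct become nonzero under the corrected branch.

The same stages are available individually (`simulate`, `select-aif`, `train-aif`,
`fit-aif`, `perfuse`, `lesions`, `validate`) and as library functions
(`ctperf.generate_phantom`, `ctperf.select_aifs`, `ctperf.predict_aif`,
`ctperf.compute_maps`, `ctperf.segment_lesions`, `ctperf.run_pipeline`, ...).

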