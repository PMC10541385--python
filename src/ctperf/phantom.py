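"""Seeded digital CTP phantoms with known ground-truth perfusion.

No public dynamic-CT stroke cohort exists at the fidelity this pipeline
needs, so validation runs on a synthetic phantom: a slab of brain tissue
with an ellipsoidal hypoperfused lesion (penumbra) containing an inner
infarct core. Each tissue class has a known CBF, MTT and arrival delay;
its concentration curve is the discrete convolution of the clean
arterial input with a flow-scaled, delayed residue function
(exponential by default, boxcar available). A small arterial block
carries the AIF itself — optionally passed through :func:`distort_aif`,
which emulates the three distortion classes seen in measured AIFs:
a drifting/noisy baseline, shape-amplitude errors of the first passage,
and a non-identical recirculation portion. Additive Gaussian noise
models CT measurement noise after standard spatial preprocessing.

Defaults: 64x64x4 voxels of 2x2x5 mm, 90 frames at 1 s; arterial bolus
K=2, AT=5 s, alpha=3, beta=1.5 s with a 20%-amplitude dispersed
recirculation 20 s later; healthy tissue 60 mL/100g/min, MTT 4 s,
delay 1 s; penumbra 25/8/8; core 8/12/10; tissue-peak SNR 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .curves import ConcentrationCurve
from .errors import ConfigError, InputError
from .gamma import GammaParams, gamma_variate

logger = logging.getLogger(__name__)

__all__ = [
    "CTPStudy",
    "GroundTruth",
    "DistortionParams",
    "ClinicalScores",
    "TissueClass",
    "PhantomConfig",
    "SEVERE_DISTORTION",
    "generate_phantom",
    "distort_aif",
    "synth_clinical_scores",
    "sample_lesion_volumes",
]


@dataclass
class CTPStudy:
    """A 4-D dynamic CT perfusion acquisition.

    Attributes
    ----------
    volume : (x, y, z, t) float array
        CT attenuation change in a.u.
    times : 1-D float array
        Acquisition time stamps (s); length equals the 4th dimension.
    spacing : (3,) float
        Voxel size in mm.
    brain_mask, artery_mask : 3-D bool arrays
        Brain parenchyma and (phantom truth) arterial voxels.
    midline_axis : int
        Axis whose midpoint splits the hemispheres.
    """

    volume: np.ndarray
    times: np.ndarray
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray
    artery_mask: np.ndarray
    midline_axis: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.volume.ndim != 4:
            raise InputError("volume must be 4-D (x, y, z, time)")
        if self.volume.shape[3] != self.times.size:
            raise InputError("4th dimension must equal len(times)")
        if any(s <= 0 for s in self.spacing):
            raise InputError("voxel spacing must be positive")
        if self.brain_mask.shape != self.volume.shape[:3]:
            raise InputError("brain_mask shape must match the spatial grid")
        if np.any(self.artery_mask & ~self.brain_mask):
            raise InputError("artery_mask must be contained in brain_mask")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class GroundTruth:
    """Phantom truth: per-voxel perfusion maps, lesion masks and the clean AIF."""

    cbf_true: np.ndarray
    mtt_true: np.ndarray
    delay_true: np.ndarray
    core_mask_true: np.ndarray
    penumbra_mask_true: np.ndarray
    aif_clean: ConcentrationCurve
    aif_params: GammaParams
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if np.any(self.core_mask_true & ~self.penumbra_mask_true):
            raise InputError("core must lie inside the penumbra")
        if np.any(self.cbf_true < 0):
            raise InputError("cbf_true must be nonnegative")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def core_volume_ml(self) -> float:
        return float(self.core_mask_true.sum() * self.voxel_volume_mm3 / 1000.0)

    @property
    def penumbra_volume_ml(self) -> float:
        return float(self.penumbra_mask_true.sum() * self.voxel_volume_mm3 / 1000.0)


@dataclass(frozen=True)
class DistortionParams:
    """Strengths of the three AIF distortion classes.

    Attributes
    ----------
    baseline_slope : float
        Linear baseline drift added over the whole curve (a.u./s).
    baseline_noise_sd : float
        SD of additive Gaussian measurement noise on the curve (a.u.).
    peak_attenuation : float in (0, 1]
        Multiplicative factor on the first-passage segment (shallow-peak
        error; 1 = unchanged).
    recirc_amplitude : float or None
        If a number, the recirculation segment is rescaled so its peak
        equals this fraction of the (distorted) first-pass peak; None
        leaves the recirculation amplitude untouched.
    recirc_jitter : float
        Half-width (s) of the uniform random time shift applied to the
        recirculation segment.

    All-zero strengths (slope 0, noise 0, attenuation 1, amplitude None,
    jitter 0) reproduce the input exactly.
    """

    baseline_slope: float = 0.0
    baseline_noise_sd: float = 0.0
    peak_attenuation: float = 1.0
    recirc_amplitude: float | None = None
    recirc_jitter: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.peak_attenuation <= 1.0):
            raise InputError("peak_attenuation must be in (0, 1]")
        if self.baseline_noise_sd < 0 or self.recirc_jitter < 0:
            raise InputError("noise and jitter amplitudes must be >= 0")
        if self.recirc_amplitude is not None and self.recirc_amplitude < 0:
            raise InputError("recirc_amplitude must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.baseline_slope == 0.0
            and self.baseline_noise_sd == 0.0
            and self.peak_attenuation == 1.0
            and self.recirc_amplitude is None
            and self.recirc_jitter == 0.0
        )


#: A distortion severe enough to defeat uncorrected deconvolution: halved
#: first-pass peak, strong baseline drift and noise, near-absent and
#: time-jittered recirculation. Used as the pipeline's hard test case.
SEVERE_DISTORTION = DistortionParams(
    baseline_slope=0.05,
    baseline_noise_sd=0.3,
    peak_attenuation=0.5,
    recirc_amplitude=0.05,
    recirc_jitter=3.0,
)

#: Strongly attenuated, noisy AIF without drift. Paired with a low-dose
#: acquisition (noise_snr ~ 5), the uncorrected kernel's noise floor
#: swamps the core/healthy CBF contrast and the reported core volume can
#: collapse to zero while the true core is present — the failure mode
#: that gamma-fit correction repairs.
OCCULT_CORE_DISTORTION = DistortionParams(
    baseline_slope=0.0,
    baseline_noise_sd=0.4,
    peak_attenuation=0.25,
    recirc_amplitude=0.05,
    recirc_jitter=3.0,
)


@dataclass(frozen=True)
class ClinicalScores:
    """Synthetic stroke-severity grades: NIHSS (0-42) and ASPECTS (0-10)."""

    nihss: int
    aspects: int

    def __post_init__(self):
        if not (0 <= self.nihss <= 42):
            raise InputError("NIHSS must be in 0..42")
        if not (0 <= self.aspects <= 10):
            raise InputError("ASPECTS must be in 0..10")


@dataclass(frozen=True)
class TissueClass:
    """Perfusion state of one tissue compartment."""

    cbf: float  # mL/100 g/min
    mtt: float  # s
    delay: float  # s


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, hemodynamics and noise of the digital phantom."""

    shape: tuple[int, int, int] = (64, 64, 4)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    dt: float = 1.0
    n_frames: int = 90
    aif_params: GammaParams = field(
        default_factory=lambda: GammaParams(K=2.0, AT=5.0, alpha=3.0, beta=1.5)
    )
    recirc_delay: float = 20.0  # s after first-pass arrival
    recirc_amplitude: float = 0.2  # fraction of first-pass peak
    recirc_alpha: float = 3.0
    recirc_beta: float = 3.0
    healthy: TissueClass = field(default_factory=lambda: TissueClass(60.0, 4.0, 1.0))
    penumbra: TissueClass = field(default_factory=lambda: TissueClass(25.0, 8.0, 8.0))
    core: TissueClass = field(default_factory=lambda: TissueClass(8.0, 12.0, 10.0))
    penumbra_volume_ml: float = 60.0
    core_volume_ml: float = 10.0
    lesion_center: tuple[int, int, int] | None = None  # None: auto, right hemisphere
    residue_model: str = "exponential"  # or "boxcar"
    noise_snr: float | None = 10.0  # healthy tissue peak / noise SD; None = noiseless
    distortion: DistortionParams | None = None
    artery_center: tuple[int, int, int] | None = None  # None: auto, left hemisphere
    artery_half_size: tuple[int, int, int] = (1, 1, 0)
    midline_axis: int = 0

    def __post_init__(self):
        if self.residue_model not in ("exponential", "boxcar"):
            raise ConfigError("residue_model must be 'exponential' or 'boxcar'")
        if self.dt <= 0 or self.n_frames < 8:
            raise ConfigError("need positive dt and at least 8 frames")
        if self.core_volume_ml > self.penumbra_volume_ml:
            raise ConfigError("core volume cannot exceed penumbra volume")


def clean_aif(config: PhantomConfig) -> ConcentrationCurve:
    """First-passage gamma variate plus a delayed, dispersed recirculation."""
    times = np.arange(config.n_frames) * config.dt
    first = gamma_variate(times, config.aif_params)
    rc_params = GammaParams(
        K=1.0,
        AT=config.aif_params.AT + config.recirc_delay,
        alpha=config.recirc_alpha,
        beta=config.recirc_beta,
    )
    rc = gamma_variate(times, rc_params).values
    if rc.max() > 0:
        rc = rc * (config.recirc_amplitude * first.values.max() / rc.max())
    return ConcentrationCurve(times, first.values + rc)


def _residue(times: np.ndarray, tc: TissueClass, model: str) -> np.ndarray:
    """Unit-height residue r(t - delay); flow scaling applied by the caller."""
    shifted = times - tc.delay
    if model == "exponential":
        return np.where(shifted >= 0, np.exp(-np.clip(shifted, 0, None) / tc.mtt), 0.0)
    return ((shifted >= 0) & (shifted < tc.mtt)).astype(float)


def _lesion_masks(
    config: PhantomConfig, brain: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Core/penumbra masks with exact voxel counts by ranked mm-distance."""
    shape = config.shape
    spacing = np.asarray(config.spacing)
    if config.lesion_center is None:
        center = (3 * shape[0] // 4, shape[1] // 2, shape[2] // 2)
    else:
        center = tuple(int(c) for c in config.lesion_center)
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ConfigError(f"lesion center {center} outside the grid {shape}")
    if not brain[center]:
        raise ConfigError(f"lesion center {center} lies outside the brain mask")

    vox_mm3 = float(np.prod(spacing))
    n_core = int(round(config.core_volume_ml * 1000.0 / vox_mm3))
    n_pen = int(round(config.penumbra_volume_ml * 1000.0 / vox_mm3))
    brain_idx = np.argwhere(brain)
    if n_pen > brain_idx.shape[0]:
        raise ConfigError("requested lesion volume exceeds the brain volume")

    d2 = (((brain_idx - np.asarray(center)) * spacing) ** 2).sum(axis=1)
    # stable ordering: distance, then lexicographic voxel index
    order = np.lexsort((brain_idx[:, 2], brain_idx[:, 1], brain_idx[:, 0], d2))
    pen_mask = np.zeros(shape, dtype=bool)
    core_mask = np.zeros(shape, dtype=bool)
    sel = brain_idx[order[:n_pen]]
    pen_mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    sel_c = brain_idx[order[:n_core]]
    core_mask[sel_c[:, 0], sel_c[:, 1], sel_c[:, 2]] = True
    return core_mask, pen_mask, center


def generate_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[CTPStudy, GroundTruth]:
    """Build a seeded digital phantom and its ground truth.

    Tissue voxels carry ``C(t) = dt * (Ca (x) CBF * r(t - delay))`` with
    the clean AIF as the true input; arterial voxels carry the clean or
    distorted AIF. Gaussian noise (SD = healthy tissue peak / noise_snr)
    is added inside the brain. Identical seeds give bit-identical output.

    Raises
    ------
    ConfigError
        Lesion placed outside the brain mask, or volumes that do not fit.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    shape = config.shape
    times = np.arange(config.n_frames) * config.dt

    # brain: axis-aligned ellipsoid at 92% of the half-extents (full slab in z
    # when the slab is thin, as in a typical 4-slice acquisition)
    half = (np.asarray(shape) - 1) / 2.0
    ijk = np.indices(shape).astype(float)
    radii = np.maximum(0.92 * half, 0.5)
    ell = sum(((ijk[a] - half[a]) / radii[a]) ** 2 for a in range(2))
    brain = ell <= 1.0  # elliptical cylinder through all slices

    core_mask, pen_mask, _ = _lesion_masks(config, brain)

    aif = clean_aif(config)
    dt = config.dt
    n = config.n_frames

    cbf_map = np.zeros(shape)
    mtt_map = np.zeros(shape)
    delay_map = np.zeros(shape)
    class_curves = {}
    for name, tc, m in (
        ("healthy", config.healthy, brain & ~pen_mask),
        ("penumbra", config.penumbra, pen_mask & ~core_mask),
        ("core", config.core, core_mask),
    ):
        F = tc.cbf / 6000.0  # mL/100g/min -> 1/s
        r = F * _residue(times, tc, config.residue_model)
        class_curves[name] = dt * np.convolve(aif.values, r)[:n]
        cbf_map[m], mtt_map[m], delay_map[m] = tc.cbf, tc.mtt, tc.delay

    volume = np.zeros(shape + (n,))
    volume[brain & ~pen_mask] = class_curves["healthy"]
    volume[pen_mask & ~core_mask] = class_curves["penumbra"]
    volume[core_mask] = class_curves["core"]

    # arterial block
    if config.artery_center is None:
        a_center = (shape[0] // 4, shape[1] // 2, shape[2] // 2)
    else:
        a_center = tuple(int(c) for c in config.artery_center)
    hs = config.artery_half_size
    sl = tuple(
        slice(max(c - h, 0), min(c + h + 1, s))
        for c, h, s in zip(a_center, hs, shape)
    )
    artery = np.zeros(shape, dtype=bool)
    artery[sl] = True
    artery &= brain
    if not artery.any():
        raise ConfigError("artery block lies outside the brain mask")

    if config.distortion is not None and not config.distortion.is_identity:
        measured = distort_aif(aif, config.distortion, seed=seed + 1)
    else:
        measured = aif
    volume[artery] = measured.values

    if config.noise_snr is not None:
        sd = class_curves["healthy"].max() / config.noise_snr
        noise = rng.normal(0.0, sd, size=volume.shape)
        volume[brain] += noise[brain]

    study = CTPStudy(
        volume=volume,
        times=times,
        spacing=config.spacing,
        brain_mask=brain,
        artery_mask=artery,
        midline_axis=config.midline_axis,
    )
    truth = GroundTruth(
        cbf_true=cbf_map,
        mtt_true=mtt_map,
        delay_true=delay_map,
        core_mask_true=core_mask,
        penumbra_mask_true=pen_mask,
        aif_clean=aif,
        aif_params=config.aif_params,
        spacing=config.spacing,
    )
    return study, truth


def distort_aif(
    curve: ConcentrationCurve, d: DistortionParams, seed: int = 0
) -> ConcentrationCurve:
    """Apply the three measurement-distortion classes to an AIF.

    The first-passage segment (arrival to the first post-peak trough) is
    scaled by ``peak_attenuation``; the recirculation segment (after the
    trough) is time-jittered and, if ``recirc_amplitude`` is set,
    rescaled to that fraction of the distorted first-pass peak; a linear
    drift ``baseline_slope * t`` and Gaussian noise are added to the
    whole curve, which is finally clipped at zero.
    """
    rng = np.random.default_rng(seed)
    t = curve.times
    v = curve.values.copy()
    if d.is_identity:
        return ConcentrationCurve(t, v)

    peak_j = int(np.argmax(v))
    fp_peak = v[peak_j]
    trough = len(v) - 1
    for i in range(peak_j + 1, len(v) - 1):
        if v[i] <= v[i - 1] and v[i] <= v[i + 1]:
            trough = i
            break
    above = np.nonzero(v > 0.10 * fp_peak)[0]
    arrival = int(above[0]) if above.size else 0

    v[arrival : trough + 1] *= d.peak_attenuation
    new_fp_peak = v[arrival : trough + 1].max() if trough > arrival else fp_peak

    if trough + 1 < len(v):
        post = v[trough + 1 :].copy()
        if d.recirc_jitter > 0:
            shift = rng.uniform(-d.recirc_jitter, d.recirc_jitter)
            ts = t[trough + 1 :]
            post = np.interp(ts, ts + shift, post, left=post[0], right=post[-1])
        if d.recirc_amplitude is not None and post.max() > 1e-12:
            post *= d.recirc_amplitude * new_fp_peak / post.max()
        v[trough + 1 :] = post

    v = v + d.baseline_slope * t
    if d.baseline_noise_sd > 0:
        v = v + rng.normal(0.0, d.baseline_noise_sd, size=v.shape)
    return ConcentrationCurve(t, np.clip(v, 0.0, None))


def synth_clinical_scores(
    truth: GroundTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    a: float = 0.15,
    b: float = 0.35,
) -> ClinicalScores:
    """Synthetic severity grades monotone in the true lesion volumes.

    NIHSS = clamp(round(a * penumbra_mL + eps), 0, 42) — rises with the
    tissue at risk; ASPECTS = clamp(10 - round(b * core_mL + eps), 0, 10)
    — falls as the infarct core grows. ``eps ~ N(0, noise_sd)`` emulates
    inter-rater variability.
    """
    rng = np.random.default_rng(seed)
    pen_ml = truth.penumbra_volume_ml
    core_ml = truth.core_volume_ml
    nihss = int(np.clip(round(a * pen_ml + rng.normal(0.0, noise_sd)), 0, 42))
    aspects = int(np.clip(10 - round(b * core_ml + rng.normal(0.0, noise_sd)), 0, 10))
    return ClinicalScores(nihss=nihss, aspects=aspects)


def sample_lesion_volumes(
    rng: np.random.Generator,
    penumbra_range: tuple[float, float] = (20.0, 180.0),
    core_fraction_range: tuple[float, float] = (0.05, 0.4),
) -> tuple[float, float]:
    """Draw a (penumbra_mL, core_mL) pair for cohort simulation.

    Penumbra volume is uniform over a plausible stroke range; the core
    is a uniform fraction of it, keeping the nesting constraint.
    """
    pen = float(rng.uniform(*penumbra_range))
    core = float(pen * rng.uniform(*core_fraction_range))
    return pen, core


def cohort_config(base: PhantomConfig, pen_ml: float, core_ml: float) -> PhantomConfig:
    """Copy of ``base`` with the given lesion volumes."""
    return replace(base, penumbra_volume_ml=pen_ml, core_volume_ml=core_ml)
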