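"""Deconvolution of tissue curves with the AIF; CBF and Tmax maps.

Per voxel, the tissue concentration curve is modeled as the convolution
of the arterial input with a flow-scaled residue function,

    C_t(t) = (C_a (x) R)(t),   R(t) = CBF * r(t - delay),

so deconvolving C_t by C_a recovers R. The deconvolution uses a
block-circulant (zero-padded to 2N) truncated-SVD formulation, which is
insensitive to the tracer arrival delay: a delayed tissue curve shifts
the recovered residue rather than corrupting it. Perfusion parameters
follow from the residue:

    CBF  = scale * max_t R(t)        (scale converts 1/s to mL/100 g/min)
    Tmax = argmax_t R(t)             (seconds; earliest time on ties)

For a circulant system the SVD coincides with the FFT diagonalization,
so the regularized inverse is applied spectrally; an explicit SVD of the
convolution matrix gives the identical operator and serves as the test
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import ConcentrationCurve, resample_uniform
from .errors import InputError

__all__ = [
    "DeconvConfig",
    "ResidueFunction",
    "PerfusionMaps",
    "deconvolve",
    "deconvolve_matrix",
    "compute_cbf",
    "compute_tmax",
    "compute_maps",
    "bolus_arrival_index",
]

#: Unit conversion from residue peak (1/s) to CBF in mL/100 g/min:
#: per-100-g and per-minute factors, 100 * 60.
CBF_SCALE_DEFAULT = 6000.0


@dataclass(frozen=True)
class DeconvConfig:
    """Regularization settings for the block-circulant truncated SVD.

    Attributes
    ----------
    truncation : float
        Singular values below ``truncation * sigma_max`` are discarded.
    pad_factor : int
        Zero-padding multiple of the curve length (2 gives the standard
        delay-insensitive block-circulant formulation).
    """

    truncation: float = 0.15
    pad_factor: int = 2

    def __post_init__(self):
        if not (0.0 <= self.truncation < 1.0):
            raise InputError("truncation must be in [0, 1)")
        if self.pad_factor < 1:
            raise InputError("pad_factor must be >= 1")


@dataclass(frozen=True)
class ResidueFunction:
    """Flow-scaled residue curve R(t) produced by deconvolution (units 1/s)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise InputError("times and values must be 1-D and equal length")
        if not np.all(np.isfinite(v)):
            raise InputError("residue values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass
class PerfusionMaps:
    """Voxelwise CBF (mL/100 g/min) and Tmax (s) maps on a brain mask."""

    cbf: np.ndarray
    tmax: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if not (self.cbf.shape == self.tmax.shape == self.mask.shape):
            raise InputError("cbf, tmax and mask must share one 3-D shape")


def _spectral_inverse(ca_pad: np.ndarray, dt: float, truncation: float) -> np.ndarray:
    """Regularized reciprocal spectrum of the circulant AIF operator.

    The circulant matrix built from the padded AIF has eigenvalues
    dt * fft(ca_pad); its singular values are their moduli. Entries whose
    modulus falls below ``truncation * sigma_max`` are zeroed in the
    inverse (truncated SVD).
    """
    g = np.fft.fft(ca_pad) * dt
    mag = np.abs(g)
    smax = mag.max()
    if smax <= 0:
        raise InputError("AIF has zero area: nothing to deconvolve")
    keep = mag >= truncation * smax
    inv = np.zeros_like(g)
    inv[keep] = 1.0 / g[keep]
    return inv


def deconvolve(
    ct: ConcentrationCurve,
    ca: ConcentrationCurve,
    reg: DeconvConfig | None = None,
) -> ResidueFunction:
    """Recover the flow-scaled residue function from tissue and arterial curves.

    Both curves must share a uniform time grid (non-uniform grids are
    resampled to the median interval first). The result satisfies
    ct ~= dt * (ca circ-conv R) in the truncated-SVD least-squares sense.

    Raises
    ------
    InputError
        Zero-area AIF, or grids that cannot be aligned.
    """
    reg = reg or DeconvConfig()
    ct, ca = _align_uniform(ct, ca)
    dt = float(ct.times[1] - ct.times[0])
    n = len(ct)
    L = reg.pad_factor * n
    ca_pad = np.zeros(L)
    ca_pad[:n] = ca.values
    ct_pad = np.zeros(L)
    ct_pad[:n] = ct.values
    inv = _spectral_inverse(ca_pad, dt, reg.truncation)
    r = np.real(np.fft.ifft(np.fft.fft(ct_pad) * inv))
    times = ct.times[0] + np.arange(L) * dt
    return ResidueFunction(times, r)


def deconvolve_matrix(
    ct: ConcentrationCurve,
    ca: ConcentrationCurve,
    reg: DeconvConfig | None = None,
) -> ResidueFunction:
    """Explicit-matrix variant: build the circulant AIF matrix and invert its SVD.

    Mathematically identical to :func:`deconvolve`; kept as an
    independent dense-linear-algebra path for cross-checking on small
    problems (O(L^3) cost).
    """
    reg = reg or DeconvConfig()
    ct, ca = _align_uniform(ct, ca)
    dt = float(ct.times[1] - ct.times[0])
    n = len(ct)
    L = reg.pad_factor * n
    ca_pad = np.zeros(L)
    ca_pad[:n] = ca.values
    ct_pad = np.zeros(L)
    ct_pad[:n] = ct.values
    if np.abs(ca_pad).sum() * dt <= 0:
        raise InputError("AIF has zero area: nothing to deconvolve")
    # circulant: column j is ca_pad rolled down by j
    A = dt * np.column_stack([np.roll(ca_pad, j) for j in range(L)])
    U, s, Vt = np.linalg.svd(A)
    keep = s >= reg.truncation * s.max()
    sinv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    r = Vt.T @ (sinv * (U.T @ ct_pad))
    times = ct.times[0] + np.arange(L) * dt
    return ResidueFunction(times, r)


def _align_uniform(
    ct: ConcentrationCurve, ca: ConcentrationCurve
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    if len(ct) != len(ca) or not np.allclose(ct.times, ca.times):
        raise InputError("tissue and arterial curves must share one time grid")
    d = np.diff(ct.times)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        ct = resample_uniform(ct)
        ca = resample_uniform(ca)
    return ct, ca


def compute_cbf(r: ResidueFunction, scale: float = CBF_SCALE_DEFAULT) -> float:
    """CBF = scale * max_t R(t); default scale 6000 yields mL/100 g/min."""
    return float(scale * r.values.max())


def compute_tmax(r: ResidueFunction, tie_tol: float = 1e-9) -> float:
    """Tmax = time of the residue maximum (s); ties break to the earliest time.

    ``tie_tol`` is the relative tolerance deciding a tie: the earliest
    sample within ``tie_tol * max`` of the maximum wins. The default only
    collapses exact-arithmetic plateaus; regularized deconvolution of a
    plateau residue (boxcar) leaves small ripples along the plateau, so
    callers recovering boxcar delays may widen it.
    """
    v = r.values
    vmax = v.max()
    j = int(np.argmax(v >= vmax - tie_tol * abs(vmax))) if vmax != 0 else 0
    return float(r.times[j])


def bolus_arrival_index(aif: ConcentrationCurve, threshold: float = 0.10) -> int:
    """First frame where the AIF exceeds ``threshold`` of its peak.

    Frames before this index form the pre-contrast baseline.
    """
    v = aif.values
    above = np.nonzero(v > threshold * v.max())[0]
    return int(above[0]) if above.size else 0


def compute_maps(
    study,
    aif: ConcentrationCurve,
    reg: DeconvConfig | None = None,
    scale: float = CBF_SCALE_DEFAULT,
) -> PerfusionMaps:
    """Voxelwise deconvolution of a 4-D study against one AIF.

    Per-voxel baselines (mean over pre-arrival frames, detected from the
    AIF) are subtracted before deconvolution. The regularized inverse of
    the circulant AIF operator is linear, so it is precomputed once
    spectrally and applied to all masked voxel curves in a single batch
    FFT. Maps are defined on the study's brain mask; voxels outside it
    are zero.

    Raises
    ------
    InputError
        If the AIF grid does not match the study's acquisition times.
    """
    reg = reg or DeconvConfig()
    times = np.asarray(study.times, dtype=float)
    if len(aif) != times.size or not np.allclose(aif.times, times):
        raise InputError("AIF must be sampled on the study's acquisition grid")

    d = np.diff(times)
    uniform = np.allclose(d, d[0], rtol=1e-6, atol=1e-9)
    vol = study.volume.astype(float)
    mask = study.brain_mask
    curves = vol[mask]  # (n_voxels, n_frames)

    if not uniform:
        dt = float(np.median(d))
        n_u = int(np.floor((times[-1] - times[0]) / dt)) + 1
        tu = times[0] + np.arange(n_u) * dt
        curves = np.apply_along_axis(lambda y: np.interp(tu, times, y), 1, curves)
        aif_v = np.interp(tu, times, aif.values)
        times = tu
    else:
        dt = float(d[0]) if d.size else 1.0
        aif_v = aif.values

    n = times.size
    aif_curve = ConcentrationCurve(times, aif_v)
    j0 = bolus_arrival_index(aif_curve)
    if j0 > 0:
        baselines = curves[:, :j0].mean(axis=1, keepdims=True)
        curves = curves - baselines
        aif_v = aif_v - aif_v[:j0].mean()

    L = reg.pad_factor * n
    ca_pad = np.zeros(L)
    ca_pad[:n] = aif_v
    inv = _spectral_inverse(ca_pad, dt, reg.truncation)

    ct_pad = np.zeros((curves.shape[0], L))
    ct_pad[:, :n] = curves
    R = np.real(np.fft.ifft(np.fft.fft(ct_pad, axis=1) * inv[None, :], axis=1))

    rmax = R.max(axis=1)
    argmax = R.argmax(axis=1)

    cbf = np.zeros(mask.shape, dtype=float)
    tmax = np.zeros(mask.shape, dtype=float)
    cbf[mask] = np.clip(scale * rmax, 0.0, None)
    tmax[mask] = np.clip(argmax * dt, 0.0, float(times[-1] - times[0]))
    return PerfusionMaps(cbf=cbf, tmax=tmax, mask=mask.copy())
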