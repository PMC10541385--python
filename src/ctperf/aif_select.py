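"""Automatic AIF voxel segmentation by recursive cluster analysis.

Arterial voxels are the earliest and sharpest curves in a region of
interest around the middle cerebral artery. Starting from all ROI voxels
with an appreciable peak, curves are normalized to unit area and
repeatedly k-means-clustered; each round keeps only the cluster whose
mean first moment (bolus center of mass) is lowest — the most arterial
one — until the candidate set is small. The final AIF candidates are the
highest-peak voxels of that set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .curves import ConcentrationCurve
from .errors import InputError, SelectionError
from .phantom import CTPStudy

__all__ = ["AIFCandidate", "ClusterConfig", "select_aifs"]


@dataclass(frozen=True)
class AIFCandidate:
    """One candidate arterial location and its concentration curve."""

    voxel_indices: tuple[tuple[int, int, int], ...]
    curve: ConcentrationCurve
    first_moment: float
    peak_value: float

    def __post_init__(self):
        if len(self.voxel_indices) == 0:
            raise InputError("candidate must reference at least one voxel")


@dataclass(frozen=True)
class ClusterConfig:
    """Recursive k-means settings for AIF segmentation."""

    k: int = 5
    min_cluster_size: int = 10
    max_rounds: int = 5
    peak_fraction: float = 0.20  # exclude voxels with peak below this x ROI max
    seed: int = 0


def _first_moments(times: np.ndarray, curves: np.ndarray) -> np.ndarray:
    """Per-curve center of mass (s), clipping negatives to zero mass."""
    w = np.clip(curves, 0.0, None)
    s = w.sum(axis=1)
    s = np.where(s > 0, s, 1.0)
    return (w * times[None, :]).sum(axis=1) / s


def _roughness(curves: np.ndarray) -> np.ndarray:
    """Sum of squared second differences; tie-breaker between clusters."""
    d2 = np.diff(curves, n=2, axis=1)
    return (d2**2).sum(axis=1)


def select_aifs(
    study: CTPStudy,
    roi: np.ndarray,
    n_aifs: int = 3,
    config: ClusterConfig | None = None,
) -> list[AIFCandidate]:
    """Segment arterial voxels in a ROI and return the best AIF candidates.

    Parameters
    ----------
    study : CTPStudy
        The dynamic acquisition.
    roi : 3-D bool array
        Region of interest (e.g. around the MCA); intersected with the
        brain mask.
    n_aifs : int
        Number of candidates to return (default 3, one AIF triple per
        dataset).
    config : ClusterConfig
        Recursion settings; the k-means seed makes selection reproducible.

    Returns
    -------
    list of AIFCandidate
        Ranked by peak value (descending) — sharp early curves first.

    Raises
    ------
    InputError
        Empty ROI.
    SelectionError
        Fewer eligible voxels than requested candidates.
    """
    config = config or ClusterConfig()
    if roi.shape != study.brain_mask.shape:
        raise InputError("roi shape must match the study grid")
    roi = roi & study.brain_mask
    if not roi.any():
        raise InputError("ROI is empty")

    times = study.times
    idx = np.argwhere(roi)
    curves = study.volume[roi].astype(float)

    peaks = curves.max(axis=1)
    eligible = peaks >= config.peak_fraction * peaks.max()
    idx = idx[eligible]
    curves = curves[eligible]
    if idx.shape[0] < n_aifs:
        raise SelectionError(
            f"only {idx.shape[0]} voxels with signal; need >= {n_aifs}"
        )

    keep = np.arange(idx.shape[0])
    for round_no in range(config.max_rounds):
        if keep.size <= max(config.min_cluster_size, n_aifs):
            break
        sub = curves[keep]
        areas = np.clip(sub, 0.0, None).sum(axis=1, keepdims=True)
        areas[areas <= 0] = 1.0
        normed = sub / areas
        # homogeneous set: nothing left to split
        if np.allclose(normed, normed[0], atol=1e-12):
            break
        k = min(config.k, keep.size)
        km = KMeans(n_clusters=k, n_init=3, random_state=config.seed + round_no)
        labels = km.fit_predict(normed)
        fm = _first_moments(times, sub)
        rough = _roughness(sub)
        best_label, best_key = None, None
        for lab in range(k):
            m = labels == lab
            if not m.any():
                continue
            key = (fm[m].mean(), rough[m].mean())
            if best_key is None or key < best_key:
                best_key, best_label = key, lab
        chosen = keep[labels == best_label]
        if chosen.size == keep.size or chosen.size < n_aifs:
            break  # no shrinkage, or would drop below the requested count
        keep = chosen

    fm = _first_moments(times, curves[keep])
    pk = curves[keep].max(axis=1)
    order = np.argsort(-pk, kind="stable")[:n_aifs]
    out = []
    for j in order:
        i = keep[j]
        out.append(
            AIFCandidate(
                voxel_indices=(tuple(int(x) for x in idx[i]),),
                curve=ConcentrationCurve(times.copy(), curves[i]),
                first_moment=float(fm[j]),
                peak_value=float(pk[j]),
            )
        )
    return out
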