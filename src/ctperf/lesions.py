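"""Core/penumbra segmentation by perfusion thresholding.

Core is tissue whose CBF falls below a fraction of a normal-tissue
reference (relative CBF < 30% at the primary threshold); penumbra is
tissue with Tmax above a delay threshold (> 6 s primary). The full
threshold families (rCBF < 20/30/38%, Tmax > 4/6/8/10 s) are reported as
a volume table in mL. The normal-tissue reference is the median CBF of
the hemisphere contralateral to the lesion (the hemisphere with the
higher median), restricted to voxels with Tmax at or below the primary
penumbra threshold; if that region is empty the whole-brain median is
used and a warning logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .perfusion import PerfusionMaps
from .phantom import CTPStudy

logger = logging.getLogger(__name__)

__all__ = ["LesionConfig", "LesionResult", "reference_cbf", "segment_lesions"]


@dataclass(frozen=True)
class LesionConfig:
    """Threshold families and the primary operating point."""

    core_rcbf_thresholds: tuple[float, ...] = (0.20, 0.30, 0.38)
    penumbra_tmax_thresholds: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0)
    primary_core: float = 0.30
    primary_penumbra: float = 6.0
    min_cluster_voxels: int = 0  # optional cleanup, off by default

    def __post_init__(self):
        if min(self.core_rcbf_thresholds + self.penumbra_tmax_thresholds) <= 0:
            raise InputError("thresholds must be positive")
        if self.primary_core not in self.core_rcbf_thresholds:
            raise InputError("primary core threshold must belong to its family")
        if self.primary_penumbra not in self.penumbra_tmax_thresholds:
            raise InputError("primary penumbra threshold must belong to its family")


@dataclass
class LesionResult:
    """Primary-threshold masks plus the full volume table (mL)."""

    core_mask: np.ndarray
    penumbra_mask: np.ndarray
    volumes_ml: dict[str, float]
    reference_cbf: float


def core_label(fraction: float) -> str:
    return f"CBF < {int(round(fraction * 100))}%"


def penumbra_label(tmax_s: float) -> str:
    return f"Tmax > {tmax_s:g} s"


def vessel_mask(study: CTPStudy, factor: float = 3.0) -> np.ndarray:
    """Voxels whose temporal peak exceeds ``factor`` x the median brain peak.

    Large vessels carry near-arterial signal; like clinical CTP software,
    parenchymal statistics exclude them (deconvolving an artery against
    itself yields a spuriously enormous CBF).
    """
    peak = study.volume.max(axis=3)
    med = float(np.median(peak[study.brain_mask]))
    return study.brain_mask & (peak > factor * med)


def reference_cbf(
    maps: PerfusionMaps,
    study: CTPStudy,
    rule: str = "contralateral_median",
    tmax_cut: float = 6.0,
) -> float:
    """Normal-tissue CBF reference for relative thresholding.

    ``contralateral_median``: split the brain at the midline, keep
    non-vessel voxels with Tmax <= ``tmax_cut`` in each hemisphere, and
    return the larger of the two median CBFs (the healthy side perfuses
    better). ``whole_brain_median`` is available directly. An empty
    reference region falls back to the whole-brain (non-vessel) median
    with a logged warning.
    """
    parenchyma = maps.mask & study.brain_mask & ~vessel_mask(study)
    if not parenchyma.any():
        parenchyma = maps.mask & study.brain_mask
    if not parenchyma.any():
        raise InputError("brain mask is empty")
    if rule == "whole_brain_median":
        return float(np.median(maps.cbf[parenchyma]))
    if rule != "contralateral_median":
        raise InputError(f"unknown reference rule: {rule}")

    axis = study.midline_axis
    mid = study.brain_mask.shape[axis] // 2
    idx = np.indices(study.brain_mask.shape)[axis]
    normal = maps.tmax <= tmax_cut
    medians = []
    for hemi in (idx < mid, idx >= mid):
        m = parenchyma & hemi & normal
        if m.any():
            medians.append(float(np.median(maps.cbf[m])))
    if not medians:
        logger.warning(
            "no normally-perfused voxels in either hemisphere; "
            "falling back to the whole-brain median CBF"
        )
        return float(np.median(maps.cbf[parenchyma]))
    return max(medians)


def segment_lesions(
    maps: PerfusionMaps,
    config: LesionConfig,
    reference: float,
    spacing: tuple[float, float, float],
) -> LesionResult:
    """Threshold the maps into core/penumbra masks and a volume table.

    Core masks use strict ``CBF < f * reference``; penumbra masks strict
    ``Tmax > tau``; both restricted to the computed-voxel mask. Volumes
    are voxel counts times the voxel volume, in mL.

    Raises
    ------
    InputError
        Non-positive reference CBF.
    """
    if reference <= 0:
        raise InputError("reference CBF must be positive")
    vox_ml = float(np.prod(spacing)) / 1000.0
    volumes: dict[str, float] = {}
    core_primary = None
    pen_primary = None
    for f in sorted(config.core_rcbf_thresholds):
        m = maps.mask & (maps.cbf < f * reference)
        volumes[core_label(f)] = float(m.sum() * vox_ml)
        if f == config.primary_core:
            core_primary = m
    for tau in sorted(config.penumbra_tmax_thresholds):
        m = maps.mask & (maps.tmax > tau)
        volumes[penumbra_label(tau)] = float(m.sum() * vox_ml)
        if tau == config.primary_penumbra:
            pen_primary = m
    return LesionResult(
        core_mask=core_primary,
        penumbra_mask=pen_primary,
        volumes_ml=volumes,
        reference_cbf=float(reference),
    )
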