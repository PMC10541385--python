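"""Synthetic AIF curve banks for training the curve-correction network.

Each simulated dataset contributes a handful of AIF curves: a clean
gamma-variate bolus (randomized amplitude, arrival and shape, plus a
dispersed recirculation) passed through a randomized measurement
distortion. The gamma fit of each distorted curve is its label, exactly
as the clustering-selected AIFs of real datasets would be curve-fitted
to build supervision. Mirror/rotate augmentation then triples the bank.
"""

from __future__ import annotations

import numpy as np

from .cnn import CurvePair, augment_pairs, make_pair
from .curves import ConcentrationCurve
from .errors import FitError
from .gamma import GammaParams, gamma_variate
from .phantom import DistortionParams

__all__ = ["sample_aif", "training_bank"]


def sample_aif(
    rng: np.random.Generator, n_frames: int = 90, dt: float = 1.0
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """One (clean, distorted) AIF draw.

    Gamma parameters vary around a typical bolus (K ~ 1.5-2.5, arrival
    3-8 s, alpha 2.5-3.5, beta 1.2-1.8 s) with a 15-25% recirculation
    18-25 s later; distortion strengths span mild to severe measurement
    error.
    """
    times = np.arange(n_frames) * dt
    params = GammaParams(
        K=rng.uniform(1.5, 2.5),
        AT=rng.uniform(3.0, 8.0),
        alpha=rng.uniform(2.5, 3.5),
        beta=rng.uniform(1.2, 1.8),
    )
    first = gamma_variate(times, params)
    rc = gamma_variate(
        times,
        GammaParams(
            K=1.0,
            AT=params.AT + rng.uniform(18.0, 25.0),
            alpha=3.0,
            beta=rng.uniform(2.5, 3.5),
        ),
    ).values
    if rc.max() > 0:
        rc *= rng.uniform(0.15, 0.25) * first.values.max() / rc.max()
    clean = ConcentrationCurve(times, first.values + rc)

    d = DistortionParams(
        baseline_slope=rng.uniform(0.0, 0.05),
        baseline_noise_sd=rng.uniform(0.05, 0.3),
        peak_attenuation=rng.uniform(0.5, 1.0),
        recirc_amplitude=rng.uniform(0.05, 0.3),
        recirc_jitter=rng.uniform(0.0, 3.0),
    )
    from .phantom import distort_aif  # circular-import-free at call time

    distorted = distort_aif(clean, d, seed=int(rng.integers(0, 2**31 - 1)))
    return clean, distorted


def training_bank(
    n_datasets: int = 128,
    n_aifs: int = 3,
    seed: int = 0,
    n_points: int = 500,
    n_frames: int = 90,
    dt: float = 1.0,
    augment: bool = True,
    include_originals: bool = False,
) -> list[CurvePair]:
    """Build the supervised curve bank.

    ``n_datasets`` simulated datasets each contribute ``n_aifs`` distorted
    curves (the defaults, 128 x 3 = 384, match a training split of that
    size); augmentation triples the count (384 -> 1152). With
    ``include_originals`` the unaugmented pairs are appended as well.

    Distorted curves whose gamma fit fails (flat or degenerate after
    distortion) are redrawn, so the bank always reaches its nominal size.
    """
    rng = np.random.default_rng(seed)
    pairs: list[CurvePair] = []
    target = n_datasets * n_aifs
    while len(pairs) < target:
        _, distorted = sample_aif(rng, n_frames=n_frames, dt=dt)
        try:
            pairs.append(make_pair(distorted, n_points=n_points))
        except FitError:
            continue
    if not augment:
        return pairs
    out = augment_pairs(pairs, seed=seed + 1)
    if include_originals:
        out = pairs + out
    return out
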