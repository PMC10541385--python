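"""Validation statistics: Spearman correlation, Bland-Altman, Wilcoxon.

Volume-score agreement uses Spearman's tie-corrected rank correlation;
paired method comparison uses Bland-Altman mean difference with 1.96-SD
limits of agreement and the two-sided Wilcoxon signed-rank test (exact
null distribution for small samples, tie-corrected normal approximation
with continuity correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError, InputError

__all__ = [
    "PairedSample",
    "StatsReport",
    "spearman",
    "bland_altman",
    "wilcoxon_signed_rank",
    "stats_report",
]

#: Sample-size cutoff below which the Wilcoxon null is enumerated exactly.
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedSample:
    """Two paired numeric vectors (e.g. volumes by two methods)."""

    a: np.ndarray
    b: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or a.shape != b.shape:
            raise InputError("paired vectors must be 1-D and equal length")
        if a.size < 3:
            raise InputError("need at least 3 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InputError("values must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class StatsReport:
    spearman_r: float
    spearman_p: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    wilcoxon_stat: float
    wilcoxon_p: float


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a t-approximation p-value.

    Raises
    ------
    InputError
        Fewer than 3 observations.
    DegenerateSampleError
        A constant vector (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("constant vector: rank correlation undefined")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def bland_altman(a, b) -> tuple[float, float, float]:
    """Mean difference and 1.96-SD limits of agreement for paired methods.

    Returns (mean_diff, loa_low, loa_high) with mean_diff = mean(a - b)
    and limits mean_diff +/- 1.96 * sd(a - b) (sample SD, n-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InputError("need two equal-length vectors with n >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 nonzero differences when ranks are untied; otherwise the
    tie-corrected normal approximation with continuity correction.

    Raises
    ------
    DegenerateSampleError
        All differences are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("need two equal-length vectors")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= WILCOXON_EXACT_MAX_N and not ties:
        method = "exact"
        res = sps.wilcoxon(d, alternative="two-sided", method=method)
    else:
        res = sps.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.statistic), float(res.pvalue)


def stats_report(sample: PairedSample) -> StatsReport:
    """All three validation statistics for one paired sample."""
    r, rp = spearman(sample.a, sample.b)
    md, lo, hi = bland_altman(sample.a, sample.b)
    ws, wp = wilcoxon_signed_rank(sample.a, sample.b)
    return StatsReport(
        spearman_r=r,
        spearman_p=rp,
        ba_mean_diff=md,
        ba_loa_low=lo,
        ba_loa_high=hi,
        wilcoxon_stat=ws,
        wilcoxon_p=wp,
    )
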