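"""Sampled contrast-concentration time curves.

The pipeline's one-dimensional currency: a time grid (seconds, strictly
increasing) paired with concentration values in arbitrary CT attenuation
units. Curves serialize to two-column CSV and to HDF5 curve banks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class ConcentrationCurve:
    """A contrast-concentration time series on an explicit time grid.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing.
    values : array of float
        Concentration at each time (a.u.), same length as ``times``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise InputError("times and values must be 1-D")
        if t.shape != v.shape:
            raise InputError(
                f"times and values lengths differ: {t.size} vs {v.size}"
            )
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InputError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise InputError("times and values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.times)))

    @property
    def peak_value(self) -> float:
        return float(self.values.max())

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.values))])

    def first_moment(self, baseline: float = 0.0) -> float:
        """Center of mass of the (baseline-subtracted, clipped) curve in seconds."""
        w = np.clip(self.values - baseline, 0.0, None)
        s = w.sum()
        if s <= 0:
            return float(self.times[-1])
        return float((self.times * w).sum() / s)

    def with_values(self, values: np.ndarray) -> "ConcentrationCurve":
        return ConcentrationCurve(self.times.copy(), np.asarray(values, dtype=float))

    # --- serialization -------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as two-column CSV with header ``time_s,value``."""
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="")

    @classmethod
    def from_csv(cls, path) -> "ConcentrationCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if arr.shape[1] != 2:
            raise InputError(f"expected two columns (time_s,value) in {path}")
        return cls(arr[:, 0], arr[:, 1])


def uniform_grid(duration: float, dt: float) -> np.ndarray:
    """Time grid 0, dt, 2*dt, ... covering [0, duration]."""
    n = int(round(duration / dt)) + 1
    return np.arange(n) * dt


def resample_uniform(curve: ConcentrationCurve) -> ConcentrationCurve:
    """Linearly resample onto a uniform grid with dt = median interval.

    Dynamic CT acquisitions sometimes have irregular time stamps; the
    deconvolution assumes a uniform grid, so curves are resampled first.
    """
    t = curve.times
    dt = float(np.median(np.diff(t)))
    n = int(np.floor((t[-1] - t[0]) / dt)) + 1
    tu = t[0] + np.arange(n) * dt
    vu = np.interp(tu, t, curve.values)
    return ConcentrationCurve(tu, vu)
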