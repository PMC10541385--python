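"""1-D convolutional network mapping distorted AIFs to gamma-fitted curves.

Measured AIF curves carry baseline drift, shallow first-pass peaks and
inconsistent recirculation. Rather than deconvolving with such a curve
directly, the pipeline trains a small convolutional network whose input
is the measured curve (spline-interpolated to a fixed 500-point grid)
and whose target is the gamma-variate fit of that curve. The output
layer is a softmax over the time grid, read as a normalized curve shape
(it sums to one); training minimizes the cross-entropy between the
unit-sum gamma label and the softmax output, and at inference the shape
is rescaled by the measured curve's first-pass area so the amplitude is
physical.

The network is implemented directly on numpy arrays: two valid-mode
convolutions (kernel length 2) with ReLU, average pooling, a 36-unit
dense layer and a dense softmax output, trained with RMSprop. The model
is small enough that explicit forward/backward passes are fast on a
single CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .curves import ConcentrationCurve
from .errors import ConfigError, InputError, StateError, TrainingError
from .gamma import fit_gamma, first_passage_window, gamma_variate
from .perfusion import bolus_arrival_index

__all__ = [
    "CurvePair",
    "CNNConfig",
    "CurveCNN",
    "interpolate_curve",
    "augment_pairs",
    "build_model",
    "train_model",
    "predict_aif",
    "make_pair",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CurvePair:
    """A training example: distorted input curve and its gamma-fit label.

    Both arrays live on the same fixed-length uniform time grid. The
    input is stored peak-normalized with the original peak recorded in
    ``normalization``; the label is normalized to unit sum (a softmax
    target).
    """

    input_values: np.ndarray
    label_values: np.ndarray
    times: np.ndarray
    normalization: float = 1.0

    def __post_init__(self):
        i = np.asarray(self.input_values, dtype=float)
        l = np.asarray(self.label_values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if not (i.shape == l.shape == t.shape) or i.ndim != 1:
            raise InputError("input, label and times must share one 1-D shape")
        if np.any(l < -1e-12):
            raise InputError("label curve must be nonnegative")
        object.__setattr__(self, "input_values", i)
        object.__setattr__(self, "label_values", np.clip(l, 0.0, None))
        object.__setattr__(self, "times", t)


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimization settings of the curve-correction CNN."""

    input_length: int = 500
    conv_kernel: int = 2
    n_conv_layers: int = 2
    conv_filters: tuple[int, ...] = (8, 16)
    pool: int = 2
    dense_units: int = 36
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "rmsprop"
    seed: int = 0

    def __post_init__(self):
        if self.input_length < 4:
            raise ConfigError("input_length must be >= 4")
        if len(self.conv_filters) != self.n_conv_layers:
            raise ConfigError("conv_filters must list one width per conv layer")
        if min(
            (self.conv_kernel, self.pool, self.dense_units, self.epochs,
             self.batch_size) + self.conv_filters
        ) < 1:
            raise ConfigError("all architecture counts must be positive")
        conv_out = self.input_length - self.n_conv_layers * (self.conv_kernel - 1)
        if conv_out < self.pool:
            raise ConfigError("pool window exceeds the post-convolution length")
        if self.optimizer != "rmsprop":
            raise ConfigError("only the rmsprop optimizer is implemented")


def interpolate_curve(curve: ConcentrationCurve, n_points: int = 500) -> ConcentrationCurve:
    """Cubic-spline resampling onto ``n_points`` uniform samples.

    The new grid spans [times[0], times[-1]]; endpoint values are
    preserved exactly and polynomials up to degree 3 are reproduced.

    Raises
    ------
    InputError
        Fewer than 4 samples (a cubic spline is underdetermined).
    """
    if len(curve) < 4:
        raise InputError("need >= 4 samples for cubic-spline interpolation")
    grid = np.linspace(curve.times[0], curve.times[-1], n_points)
    spl = CubicSpline(curve.times, curve.values)
    vals = spl(grid)
    vals[0], vals[-1] = curve.values[0], curve.values[-1]
    return ConcentrationCurve(grid, vals)


# --- augmentation ------------------------------------------------------


def _mirror(values: np.ndarray, pivot: int) -> np.ndarray:
    """Reflect about the vertical line through ``pivot``, clamping to the grid."""
    n = values.size
    src = np.clip(2 * pivot - np.arange(n), 0, n - 1)
    return values[src]


def _rotate(values: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate the (t, value) polyline about its centroid; re-interpolate.

    The polyline is normalized to the unit square first so the angle is
    unit-free; the result is mapped back and clipped at zero.
    """
    n = values.size
    vmax = np.abs(values).max()
    if vmax <= 0:
        return values.copy()
    x = np.linspace(0.0, 1.0, n)
    y = values / vmax
    cx, cy = x.mean(), y.mean()
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    xr = cx + c * (x - cx) - s * (y - cy)
    yr = cy + s * (x - cx) + c * (y - cy)
    order = np.argsort(xr, kind="stable")
    out = np.interp(x, xr[order], yr[order])
    return np.clip(out * vmax, 0.0, None)


def augment_pairs(
    pairs: list[CurvePair], seed: int = 0, max_angle_deg: float = 5.0
) -> list[CurvePair]:
    """Mirror, rotate, and mirror+rotate every pair: 3 outputs per input.

    The mirror reflects both curves about the input curve's global peak;
    the rotation turns the (t, value) polyline by an angle drawn
    uniformly within +/- ``max_angle_deg`` about its centroid (a fresh
    angle for the combined transform). Input and label receive identical
    transform parameters.

    Raises
    ------
    InputError
        Empty input list.
    """
    if not pairs:
        raise InputError("no pairs to augment")
    rng = np.random.default_rng(seed)
    out: list[CurvePair] = []
    amax = np.deg2rad(max_angle_deg)
    for p in pairs:
        pivot = int(np.argmax(p.input_values))
        mirrored = replace(
            p,
            input_values=_mirror(p.input_values, pivot),
            label_values=_mirror(p.label_values, pivot),
        )
        th1 = rng.uniform(-amax, amax)
        rotated = replace(
            p,
            input_values=_rotate(p.input_values, th1),
            label_values=_rotate(p.label_values, th1),
        )
        th2 = rng.uniform(-amax, amax)
        both = replace(
            mirrored,
            input_values=_rotate(mirrored.input_values, th2),
            label_values=_rotate(mirrored.label_values, th2),
        )
        out.extend([mirrored, rotated, both])
    return out


def make_pair(
    raw_curve: ConcentrationCurve, n_points: int = 500
) -> CurvePair:
    """Build one training pair: interpolated input + gamma-fit label.

    The gamma model is fitted to the raw curve over its first-passage
    window; the label is the fitted model evaluated on the interpolation
    grid and normalized to unit sum. The input is peak-normalized, the
    peak recorded in ``normalization``.
    """
    interp = interpolate_curve(raw_curve, n_points)
    params, _ = fit_gamma(raw_curve)
    label = gamma_variate(interp.times, params).values
    lsum = label.sum()
    if lsum <= 0:
        raise InputError("degenerate gamma fit: label has zero mass")
    peak = np.abs(interp.values).max()
    peak = peak if peak > 0 else 1.0
    return CurvePair(
        input_values=interp.values / peak,
        label_values=label / lsum,
        times=interp.times,
        normalization=float(peak),
    )


# --- the network -------------------------------------------------------


class CurveCNN:
    """Numpy implementation of the curve-correction network.

    Parameters are initialized Glorot-uniform from the config seed, so
    two builds with the same config are bit-identical.
    """

    def __init__(self, config: CNNConfig):
        self.config = config
        self.trained = False
        self.history: list[float] = []
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        k = config.conv_kernel
        in_ch = 1
        length = config.input_length
        for i, f in enumerate(config.conv_filters):
            self.params[f"Wc{i}"] = self._glorot(rng, (k, in_ch, f), k * in_ch, k * f)
            self.params[f"bc{i}"] = np.zeros(f)
            in_ch = f
            length -= k - 1
        pooled = length // config.pool
        flat = pooled * in_ch
        self.params["Wd0"] = self._glorot(rng, (flat, config.dense_units), flat, config.dense_units)
        self.params["bd0"] = np.zeros(config.dense_units)
        self.params["Wd1"] = self._glorot(
            rng, (config.dense_units, config.input_length),
            config.dense_units, config.input_length,
        )
        self.params["bd1"] = np.zeros(config.input_length)
        self._pooled_len = pooled
        self._conv_out_len = length
        self._cache_rms: dict[str, np.ndarray] = {
            n: np.zeros_like(p) for n, p in self.params.items()
        }

    @staticmethod
    def _glorot(rng, shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # forward ----------------------------------------------------------

    def _conv(self, x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Valid 1-D convolution; x (B, L, Cin), W (k, Cin, Cout)."""
        k = W.shape[0]
        L = x.shape[1] - k + 1
        out = np.tensordot(x[:, 0:L, :], W[0], axes=([2], [0]))
        for j in range(1, k):
            out += np.tensordot(x[:, j : j + L, :], W[j], axes=([2], [0]))
        return out + b

    def forward(self, x: np.ndarray, cache: bool = False):
        """x: (B, input_length) -> softmax probabilities (B, input_length)."""
        cfg = self.config
        a = x[:, :, None]
        caches = {"inputs": [a], "pre": []}
        for i in range(cfg.n_conv_layers):
            z = self._conv(a, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            a = np.maximum(z, 0.0)
            caches["pre"].append(z)
            caches["inputs"].append(a)
        p = cfg.pool
        m = self._pooled_len
        pooled = a[:, : m * p, :].reshape(a.shape[0], m, p, -1).mean(axis=2)
        flat = pooled.reshape(a.shape[0], -1)
        zd0 = flat @ self.params["Wd0"] + self.params["bd0"]
        h = np.maximum(zd0, 0.0)
        logits = h @ self.params["Wd1"] + self.params["bd1"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        norm = e.sum(axis=1, keepdims=True)
        q = e / norm
        if cache:
            # log-softmax kept for an exactly differentiable cross-entropy
            caches.update(flat=flat, zd0=zd0, h=h, q=q,
                          logq=logits - np.log(norm))
            return q, caches
        return q

    # backward + RMSprop -------------------------------------------------

    def _backward(self, caches: dict, labels: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        B = labels.shape[0]
        q = caches["q"]
        grads: dict[str, np.ndarray] = {}
        dlogits = (q - labels) / B
        grads["Wd1"] = caches["h"].T @ dlogits
        grads["bd1"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wd1"].T
        dzd0 = dh * (caches["zd0"] > 0)
        grads["Wd0"] = caches["flat"].T @ dzd0
        grads["bd0"] = dzd0.sum(axis=0)
        dflat = dzd0 @ self.params["Wd0"].T

        p = cfg.pool
        m = self._pooled_len
        f_last = cfg.conv_filters[-1]
        dpooled = dflat.reshape(B, m, f_last)
        da = np.zeros((B, self._conv_out_len, f_last))
        da[:, : m * p, :] = np.repeat(dpooled / p, p, axis=1)

        for i in reversed(range(cfg.n_conv_layers)):
            z = caches["pre"][i]
            x_in = caches["inputs"][i]
            dz = da * (z > 0)
            k = cfg.conv_kernel
            L = dz.shape[1]
            W = self.params[f"Wc{i}"]
            gW = np.zeros_like(W)
            dx = np.zeros_like(x_in)
            for j in range(k):
                gW[j] = np.tensordot(x_in[:, j : j + L, :], dz, axes=([0, 1], [0, 1]))
                dx[:, j : j + L, :] += np.tensordot(dz, W[j], axes=([2], [1]))
            grads[f"Wc{i}"] = gW
            grads[f"bc{i}"] = dz.sum(axis=(0, 1))
            da = dx
        return grads

    def _rmsprop_step(self, grads: dict[str, np.ndarray], lr: float,
                      rho: float = 0.9, eps: float = 1e-7) -> None:
        for name, g in grads.items():
            c = self._cache_rms[name]
            c *= rho
            c += (1.0 - rho) * g * g
            self.params[name] -= lr * g / (np.sqrt(c) + eps)

    def loss(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Mean cross-entropy between unit-sum labels and softmax outputs."""
        _, caches = self.forward(x, cache=True)
        return float(-(labels * caches["logq"]).sum(axis=1).mean())


def build_model(config: CNNConfig | None = None) -> CurveCNN:
    """Construct the untrained network; same seed gives identical weights."""
    return CurveCNN(config or CNNConfig())


def _stack_pairs(pairs: list[CurvePair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input_values for p in pairs])
    y = np.stack([p.label_values for p in pairs])
    ysum = y.sum(axis=1, keepdims=True)
    ysum[ysum <= 0] = 1.0
    return x, y / ysum


def train_model(
    model: CurveCNN,
    pairs: list[CurvePair],
    config: CNNConfig | None = None,
) -> tuple[CurveCNN, list[float]]:
    """Train in place with RMSprop; returns the model and per-epoch losses.

    Labels are (re)normalized to unit sum. Shuffling is driven by the
    config seed, so training is reproducible on a fixed device and
    precision.

    Raises
    ------
    InputError
        Fewer pairs than one batch.
    TrainingError
        Non-finite loss (divergence).
    """
    cfg = config or model.config
    if len(pairs) < cfg.batch_size:
        raise InputError(
            f"need at least one batch ({cfg.batch_size}) of pairs, got {len(pairs)}"
        )
    x, y = _stack_pairs(pairs)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[float] = []
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            q, caches = model.forward(x[sel], cache=True)
            batch_loss = -(y[sel] * caches["logq"]).sum(axis=1).mean()
            if not np.isfinite(batch_loss):
                raise TrainingError("training diverged: non-finite loss")
            losses.append(batch_loss)
            grads = model._backward(caches, y[sel])
            model._rmsprop_step(grads, cfg.learning_rate)
        history.append(float(np.mean(losses)))
    model.trained = True
    model.history = history
    return model, history


def first_pass_area(curve: ConcentrationCurve) -> float:
    """Area (a.u.*s) under the baseline-corrected first passage.

    Baseline is the mean of pre-arrival samples (arrival = first sample
    above 10% of peak); the window runs to the first post-peak local
    minimum.
    """
    j0 = bolus_arrival_index(curve)
    baseline = curve.values[:j0].mean() if j0 > 0 else 0.0
    vb = np.clip(curve.values - baseline, 0.0, None)
    corrected = ConcentrationCurve(curve.times, vb)
    lo, hi = first_passage_window(corrected)
    sel = (curve.times >= lo) & (curve.times <= hi)
    if sel.sum() < 2:
        return float(np.trapezoid(vb, curve.times))
    return float(np.trapezoid(vb[sel], curve.times[sel]))


def predict_aif(model: CurveCNN, raw_curve: ConcentrationCurve) -> ConcentrationCurve:
    """Map a measured AIF through the trained network.

    The curve is interpolated to the network grid and peak-normalized;
    the softmax output (a unit-sum shape) is rescaled so its integral
    equals the measured curve's first-pass area, then mapped back onto
    the native time grid. The result is nonnegative everywhere.

    Raises
    ------
    StateError
        Untrained model.
    """
    if not model.trained:
        raise StateError("model is untrained; call train_model first (train-aif)")
    interp = interpolate_curve(raw_curve, model.config.input_length)
    peak = np.abs(interp.values).max()
    x = interp.values / (peak if peak > 0 else 1.0)
    q = model.forward(x[None, :])[0]
    area = first_pass_area(raw_curve)
    dt_grid = (interp.times[-1] - interp.times[0]) / (len(interp) - 1)
    phys = q * (area / dt_grid if dt_grid > 0 else 1.0)
    native = np.interp(raw_curve.times, interp.times, phys)
    return ConcentrationCurve(raw_curve.times, np.clip(native, 0.0, None))


# --- persistence -------------------------------------------------------


def save_model(model: CurveCNN, path) -> None:
    """Save config + weights (+ training history) as a compressed npz."""
    blob = {f"param_{k}": v for k, v in model.params.items()}
    blob["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    blob["trained"] = np.array([int(model.trained)])
    blob["history"] = np.asarray(model.history, dtype=float)
    np.savez_compressed(path, **blob)


def load_model(path) -> CurveCNN:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
        model = CurveCNN(CNNConfig(**cfg_dict))
        for k in model.params:
            model.params[k] = data[f"param_{k}"]
        model.trained = bool(data["trained"][0])
        model.history = list(data["history"])
    return model
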