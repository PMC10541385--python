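"""Exception hierarchy for the ctperf pipeline."""


class CTPerfError(Exception):
    """Base class for all ctperf errors."""


class InputError(CTPerfError, ValueError):
    """Invalid input data (non-increasing time grid, empty ROI, grid mismatch...)."""


class ConfigError(CTPerfError, ValueError):
    """Inconsistent configuration (lesion outside brain, pool larger than sequence...)."""


class FitError(CTPerfError):
    """Curve fitting failed on a degenerate input (flat curve, no dynamic range)."""


class ConvergenceError(FitError):
    """Fit did not converge; carries the best parameters found so far."""

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics


class SelectionError(CTPerfError):
    """AIF selection could not find enough eligible voxels."""


class TrainingError(CTPerfError):
    """Model training diverged (non-finite loss)."""


class StateError(CTPerfError, RuntimeError):
    """Operation requires state that is missing (e.g. an untrained model)."""


class DegenerateSampleError(CTPerfError, ValueError):
    """A statistic is undefined on this sample (constant vector, all-zero differences)."""
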