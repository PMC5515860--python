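"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PipelineError, ValueError):
    """A configuration object is internally inconsistent (bad timings, overlapping ROIs, ...)."""


class InputError(PipelineError, ValueError):
    """Input data violate a stage precondition (grid mismatch, too few pairs, empty mask, ...)."""


class CalibrationError(PipelineError, RuntimeError):
    """A calibration signal is unusable (non-positive CSF magnetization, all-zero coil scan, ...)."""


class ConvergenceError(PipelineError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
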