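"""Exception hierarchy."""


class SFBDError(Exception):
    """Base class for package errors."""


class GeometryError(SFBDError):
    """Degenerate or inconsistent molecular geometry."""


class TopologyError(SFBDError):
    """Invalid bond topology (e.g. disconnected graph)."""


class ModelError(SFBDError):
    """Inconsistent or non-positive-definite model."""


class StepSizeError(SFBDError):
    """Integration step too large (quaternion renormalization failed or the
    internal coordinates left the physically plausible region)."""


class FitError(SFBDError):
    """Multiexponential fit failed to converge."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ConfigError(SFBDError):
    """Malformed run configuration."""
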