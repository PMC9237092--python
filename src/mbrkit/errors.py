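"""Exception types shared across the package."""


class MbrkitError(Exception):
    """Base class for package errors."""


class InputError(MbrkitError, ValueError):
    """Raised when an input value or selection is invalid."""


class GeometryError(MbrkitError, ValueError):
    """Raised when a geometric operation is degenerate (e.g. collinear plane fit)."""


class ConfigError(MbrkitError, ValueError):
    """Raised when a pipeline configuration fails validation.

    Carries every individual failure so a run can report them all at once.
    """

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__("invalid configuration: " + "; ".join(self.failures))
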