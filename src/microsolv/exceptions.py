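"""Exception hierarchy for microsolv."""


class MicrosolvError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MicrosolvError, ValueError):
    """A physical parameter is out of its admissible range."""


class PreconditionError(MicrosolvError, ValueError):
    """An operation's stated precondition is violated."""


class GridResolutionError(PreconditionError):
    """A time grid is too coarse for the requested operation."""


class ExtrapolationError(MicrosolvError, ValueError):
    """A requested delay lies outside the integrated/simulated range."""


class BinningError(MicrosolvError, ValueError):
    """Spectra with mismatched energy binning were combined."""


class InsufficientSignalError(MicrosolvError, ValueError):
    """A spectrum carries too little positive signal to be fitted."""


class AliasingError(PreconditionError):
    """An oscillation fit was attempted on an undersampled curve."""


class FitError(MicrosolvError, RuntimeError):
    """A nonlinear fit failed to converge or produced no covariance."""


class ConfigError(MicrosolvError, ValueError):
    """A run configuration is malformed."""
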