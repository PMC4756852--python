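"""Exception hierarchy shared across the package."""


class LaserDDRError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(LaserDDRError, ValueError):
    """An argument violates a precondition (wrong sign, shape, or token)."""


class OutOfRangeError(LaserDDRError, ValueError):
    """A power setting falls outside the calibration domain; no extrapolation."""


class DegenerateInputError(LaserDDRError, ValueError):
    """Input is formally valid but numerically degenerate (e.g. zero background)."""


class FitFailureError(LaserDDRError, RuntimeError):
    """A least-squares fit did not converge; carries diagnostics in args."""


class ConfigurationError(LaserDDRError, ValueError):
    """Configuration file failed validation; message lists offending keys."""
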