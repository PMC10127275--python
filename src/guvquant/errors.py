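"""Exception hierarchy shared across the package.

Configuration problems (bad parameter values, malformed config files) raise
:class:`ConfigurationError`; problems with the data being analysed (missing
standards, saturated signals, degenerate fits) raise :class:`DataError`
subclasses.  The command-line layer maps these onto exit codes 2 and 3.
"""


class GuvQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GuvQuantError, ValueError):
    """Invalid parameter value or malformed configuration."""


class PlacementError(GuvQuantError, RuntimeError):
    """Vesicle placement failed after bounded retries (field too crowded)."""


class DataError(GuvQuantError, RuntimeError):
    """Problem with input data rather than configuration."""


class InsufficientDataError(DataError):
    """Not enough points / dynamic range to perform a fit."""


class FitError(DataError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


class SaturatedSignalError(DataError):
    """Observed count at or above the saturation asymptote; inversion undefined."""


class DenseCountError(DataError):
    """Dense-regime count requested without a single-molecule intensity reference."""


class MissingStandardsError(DataError):
    """Calibration standards absent; absolute quantification impossible."""
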