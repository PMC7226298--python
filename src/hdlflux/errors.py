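"""Exception hierarchy shared across the package.

Everything derives from :class:`HdlFluxError` so callers can catch the
package's failures with one clause; most are also ``ValueError`` subclasses
because they signal bad inputs.
"""


class HdlFluxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HdlFluxError, ValueError):
    """A numeric argument is outside its admissible range."""


class InvalidSequenceError(HdlFluxError, ValueError):
    """A peptide string contains a non-standard residue."""


class InvalidInputError(HdlFluxError, ValueError):
    """Structurally inconsistent inputs (e.g. mismatched peak counts)."""


class ConfigurationError(HdlFluxError, ValueError):
    """A configuration table or run config is incomplete or contradictory."""


class DegenerateDataError(HdlFluxError, ValueError):
    """Data carry no usable variation (constant sample, zero variance)."""


class DegenerateCalibrationError(DegenerateDataError):
    """Calibration levels cannot identify a line (fewer than 2 distinct)."""


class MissingDataError(HdlFluxError, ValueError):
    """A required observation or covariate is absent."""
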