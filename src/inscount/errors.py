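"""Exception hierarchy for pipeline errors.

Validation and format errors are raised while reading inputs; the
remaining classes map to specific analysis stages so the CLI can
distinguish bad inputs (exit code 2) from runtime failures (exit code 1).
"""


class InscountError(Exception):
    """Base class for all package errors."""


class FormatError(InscountError):
    """A file is malformed (missing column, non-numeric cell, ...)."""


class ValidationError(InscountError):
    """Input parsed but violates a domain invariant."""


class NormalizationError(InscountError):
    """A sample cannot be normalized (e.g. zero control sum)."""


class BackgroundModelError(InscountError):
    """A background threshold cannot be estimated."""


class FitError(InscountError):
    """A regression / standard-curve fit is infeasible or invalid."""


class AlignmentError(InscountError):
    """Two profiles cannot be aligned (mismatched genes or groups)."""


class ConfigError(InscountError):
    """A pipeline configuration is invalid."""
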