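"""Exception and warning hierarchy.

Everything raised on purpose derives from :class:`FoldkinError`, so callers
can catch the package's failures without masking programming errors.
"""


class FoldkinError(Exception):
    """Base class for all errors raised by foldkin."""


class InvalidParameterError(FoldkinError, ValueError):
    """A kinetic parameter or input value violates its domain constraints."""


class DataError(FoldkinError, ValueError):
    """Malformed or insufficient input data (schema errors, too few points)."""


class AlignmentError(DataError):
    """Traces that should share a time base or metadata do not."""


class StateError(FoldkinError, RuntimeError):
    """An operation was called before its prerequisites were established."""


class FitFailureError(FoldkinError, RuntimeError):
    """A least-squares fit did not converge after multistart."""


class NoAmplitudeError(FitFailureError):
    """A fluorescence trace carries no resolvable exponential signal."""


class DegenerateGeometryError(FoldkinError, ValueError):
    """m-value geometry is degenerate (m_D-N = 0), betas are undefined."""


class IntegrityError(DataError):
    """A packaged data file does not match its recorded checksum."""


class DegeneracyWarning(UserWarning):
    """The fit Jacobian is (nearly) singular; named parameters are unreliable."""


class BetaRangeWarning(UserWarning):
    """A Tanford beta value fell outside the nominal [0, 1] range."""
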