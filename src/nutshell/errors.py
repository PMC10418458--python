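"""Typed exceptions raised throughout the package.

Every malformed input maps to one of these; nothing is silently coerced.
"""


class NutshellError(Exception):
    """Base class for all package errors."""


class GridError(NutshellError):
    """Wavenumber grid is malformed (non-monotone, uneven spacing, gaps)."""


class ValidationError(NutshellError):
    """Input data violates a structural invariant (ids, roles, joins)."""


class InfeasibleDesignError(NutshellError):
    """Requested mixture design cannot satisfy its constraints.

    The message names the violated constraint.
    """


class DegenerateFitError(NutshellError):
    """A least-squares fit is degenerate (zero-variance reference, |b| ~ 0)."""


class PipelineError(NutshellError):
    """A pipeline stage failed; the stage name is carried in the message."""
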