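"""Exception hierarchy for ctcflow.

All errors derive from :class:`CtcflowError` so callers can catch the
package's failures with one clause; the subclasses distinguish bad
parameters, structurally inconsistent inputs, degenerate data (e.g. a
silent pool producing a zero-variance series) and numerical failures of
the integrator.
"""


class CtcflowError(Exception):
    """Base class for all ctcflow errors."""


class ParameterError(CtcflowError, ValueError):
    """A parameter value violates its documented constraint."""


class StructuralError(CtcflowError, ValueError):
    """Inputs are mutually inconsistent (shape/length/schema mismatch)."""


class DegenerateInputError(CtcflowError, ValueError):
    """Input is formally valid but carries no usable signal."""


class DataError(CtcflowError, ValueError):
    """Not enough data to compute the requested quantity."""


class IntegrationError(CtcflowError, RuntimeError):
    """The network integration diverged."""


class UndefinedMeanError(CtcflowError, ValueError):
    """Circular mean undefined (resultant vector numerically zero)."""
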