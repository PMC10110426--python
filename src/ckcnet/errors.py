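"""Exception hierarchy used across the package.

All errors derive from :class:`CkcError` so callers can catch one base
class; most are also ``ValueError`` subclasses because they signal bad
arguments or degenerate inputs rather than internal failures.
"""


class CkcError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CkcError, ValueError):
    """A parameter is outside its documented domain."""


class UnknownChannelError(CkcError, KeyError):
    """A channel label is not part of the recording montage."""


class MontageError(CkcError, ValueError):
    """A channel lacks an electrode position."""


class AliasingError(CkcError, ValueError):
    """Requested filter band violates the Nyquist limit."""


class EmptyEpochsError(CkcError, ValueError):
    """No epoch survives extraction or rejection."""


class InsufficientTrialsError(CkcError, ValueError):
    """Fewer trials than the statistic requires (N >= 2)."""


class DegenerateSignalError(CkcError, ValueError):
    """A signal is constant/zero where variability is required."""


class NumericalError(CkcError, RuntimeError):
    """A linear system is too ill-conditioned to solve reliably."""


class IncompatibleInputsError(CkcError, ValueError):
    """Inputs that must share shape/mask/labels do not."""


class MissingControlError(CkcError, ValueError):
    """No control recording available; reference distribution undefined."""


class UndefinedMetricError(CkcError, ValueError):
    """A ratio metric is undefined (e.g. both inputs zero)."""
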