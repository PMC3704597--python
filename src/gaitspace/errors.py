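"""Domain-specific exceptions.

All inherit from :class:`GaitspaceError` so callers can catch the package's
failures with one clause; most also subclass a fitting builtin.
"""


class GaitspaceError(Exception):
    """Base class for all gaitspace errors."""


class ShapeError(GaitspaceError, ValueError):
    """Trial or matrix dimensions are inconsistent with the declared layout."""


class EmptyDataError(GaitspaceError, ValueError):
    """An operation received no data."""


class DegenerateVariableError(GaitspaceError, ValueError):
    """A subject/variable has zero standard deviation and cannot be whitened."""


class DegenerateDataError(GaitspaceError, ValueError):
    """The data carry no usable variance (e.g. all-zero matrix)."""


class NoStanceError(GaitspaceError, ValueError):
    """No frame of the force trace reaches the stance threshold."""


class FoldRankError(GaitspaceError, ValueError):
    """A leave-one-subject-out fold has lower rank than the requested component."""


class BasisError(GaitspaceError, ValueError):
    """A vector set violates the orthonormality required of a basis."""


class StateError(GaitspaceError, RuntimeError):
    """An operation was called in the wrong state (e.g. missing whitening stats)."""


class ConvergenceError(GaitspaceError, RuntimeError):
    """An iterative solver failed to converge."""
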