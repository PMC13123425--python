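"""Exception hierarchy shared across the package.

All package errors derive from :class:`A2MechError`, so callers can catch a
single base class. Domain errors signal physically meaningless arguments,
input errors signal malformed or under-determined data, and fit errors signal
optimizer failure (they carry whatever diagnostics the backend produced).
"""


class A2MechError(Exception):
    """Base class for every error raised by a2mech."""


class DomainError(A2MechError, ValueError):
    """Argument outside the physical domain of a model (e.g. x >= Lc)."""


class InputError(A2MechError, ValueError):
    """Malformed, inconsistent, or under-determined input data."""


class DegenerateParametersError(DomainError):
    """Two parameter sets that cannot be distinguished by the requested
    computation (e.g. equal barrier positions in a crossover solve)."""


class NoEventError(A2MechError, ValueError):
    """A simulation that can never produce an event (zero unfolding rate)."""


class FitError(A2MechError, RuntimeError):
    """Nonlinear least squares failed to converge or produced a degenerate
    solution; the message carries the backend diagnostics."""


class SchemaError(InputError):
    """A delimited-text table is missing required columns."""


class ValidationError(InputError):
    """A table parsed but violated a structural invariant (e.g. a trace
    whose time stamps are not strictly increasing)."""
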