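"""Exception hierarchy.

All package errors derive from :class:`BtbpkError` so callers can catch one
base class; configuration problems (missing constants, invalid records) are
kept distinct from estimation failures.
"""


class BtbpkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BtbpkError):
    """A model spec, record or config document is invalid or incomplete."""


class DomainError(BtbpkError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class EstimationError(BtbpkError):
    """A fit could not be performed or did not converge."""

    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces


class SimulationError(BtbpkError):
    """The integrator failed; carries the last state and tolerances."""

    def __init__(self, message, state=None, rtol=None, atol=None):
        super().__init__(message)
        self.state = state
        self.rtol = rtol
        self.atol = atol
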