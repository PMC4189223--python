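"""Exception hierarchy shared across breathloop modules."""


class BreathloopError(Exception):
    """Base class for all breathloop errors."""


class InvalidInputError(BreathloopError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedMetricError(BreathloopError, ValueError):
    """A metric is mathematically undefined for the given input
    (e.g. coefficient of variation of a signal with non-positive mean)."""


class IntegrationError(BreathloopError, RuntimeError):
    """The closed-loop integrator produced a non-finite or
    non-physical state; the message names the offending quantity."""


class InvalidCallError(BreathloopError, RuntimeError):
    """A streaming interface was called out of contract
    (e.g. non-monotone timestamps fed to the tracker)."""


class NoResponseError(BreathloopError, RuntimeError):
    """A response signal never crossed the detection threshold."""
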