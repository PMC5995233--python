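"""Exception hierarchy shared across the toolkit."""


class PanelvalError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(PanelvalError, ValueError):
    """Invalid user-supplied parameter."""


class ConsistencyError(PanelvalError, ValueError):
    """Inputs that should agree (sites, gene sets) do not."""


class CapacityError(PanelvalError, ValueError):
    """Request exceeds what the reference/panel can supply."""


class DegenerateInputError(PanelvalError, ValueError):
    """Input with no usable signal (e.g. zero normal depth)."""


class UndefinedMetricError(PanelvalError, ZeroDivisionError):
    """A rate whose denominator is zero."""
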