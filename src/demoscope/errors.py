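"""Exception hierarchy shared across demoscope."""


class DemoscopeError(Exception):
    """Base class for all demoscope errors."""


class InvalidInputError(DemoscopeError, ValueError):
    """A caller-supplied value violates an operation's preconditions."""


class FormatError(DemoscopeError, ValueError):
    """A file or table does not conform to its declared format."""


class UnsupportedFeatureError(DemoscopeError, NotImplementedError):
    """The request is well-formed but outside this implementation's scope."""


class InsufficientDataError(DemoscopeError, ValueError):
    """Not enough observations to compute the requested summary."""


class DegenerateSpectrumError(DemoscopeError, ValueError):
    """A spectrum transform would leave no probability mass."""
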