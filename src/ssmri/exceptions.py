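"""Exception types shared across the package."""


class ShapeError(ValueError):
    """Array shapes are inconsistent with the operation's contract."""


class ConfigurationError(ValueError):
    """A configuration object or parameter set is invalid."""


class StateError(RuntimeError):
    """An operation was requested in an invalid object state."""


class InvalidKernelError(ValueError):
    """A convolution kernel violates the odd-size requirement."""
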