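class BoolhubError(Exception):
    """Base class for all boolhub errors."""


class ConfigurationError(BoolhubError, ValueError):
    """A configuration value violates an invariant; the message names it."""


class DataError(BoolhubError, ValueError):
    """An input matrix or table violates its contract."""


class ConvergenceError(BoolhubError, RuntimeError):
    """An iterative solver failed to converge within its budget."""
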