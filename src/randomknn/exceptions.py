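"""Exception hierarchy shared across the package."""


class RandomKnnError(Exception):
    """Base class for all package-specific errors."""


class DataError(RandomKnnError, ValueError):
    """Invalid dataset content: bad shapes, missing values, too few classes."""


class ConfigError(RandomKnnError, ValueError):
    """Invalid configuration: unknown columns, unreadable files, bad flags."""


class ParameterError(RandomKnnError, ValueError):
    """Invalid algorithm parameter: k too large, m > p, q outside (0, 1)."""


class StateError(RandomKnnError, RuntimeError):
    """A computation reached a state it cannot proceed from."""
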