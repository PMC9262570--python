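"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An architecture or algorithm configuration is invalid."""


class DimensionMismatchError(ValueError):
    """A weight vector's length does not match the architecture."""


class InputError(ValueError):
    """An input array is malformed (wrong shape, NaN, out of range)."""


class DataError(ValueError):
    """A dataset violates a structural requirement (e.g. single class)."""


class EpisodeStateError(RuntimeError):
    """An environment operation was attempted in an invalid episode state."""
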