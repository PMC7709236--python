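"""Exception types shared across the package."""


class ParameterFormatError(ValueError):
    """A parameter file failed to parse or contained unknown keys."""


class ParameterValidationError(ValueError):
    """A parameter set violated a model invariant."""


class DataError(ValueError):
    """Bundled or user-supplied data is incomplete (e.g. a life-table gap)."""


class ConfigurationError(ValueError):
    """A scenario/PSA configuration referenced an unknown parameter path."""
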