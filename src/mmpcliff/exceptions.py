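"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A required column, option or model/kernel combination is wrong."""


class InputError(ValueError):
    """The input data itself is unusable (empty file, duplicate ids, ...)."""
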