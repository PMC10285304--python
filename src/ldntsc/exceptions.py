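"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A model, training, or CLI configuration is invalid."""


class DataError(ValueError):
    """Input data violates a contract (non-finite values, bad labels, ...)."""


class FormatError(ValueError):
    """A data file does not parse under the requested dialect."""
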