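"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent (names the offending field)."""


class ValidationError(ValueError):
    """Input data violate a contract (missing masks, duplicate paths, ...)."""
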