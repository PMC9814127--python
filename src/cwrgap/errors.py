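"""Exception types used across the pipeline."""


class ValidationError(ValueError):
    """Input data violates a structural contract (bad geometry, bad enum...)."""


class ConfigurationError(ValueError):
    """A configuration value is unusable (unknown dialect, bad threshold...)."""
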