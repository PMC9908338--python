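class ConfigError(ValueError):
    """A configuration violates one of its documented bounds."""


class DataError(ValueError):
    """Input data violates a structural invariant (shapes, vocabularies, spans)."""
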