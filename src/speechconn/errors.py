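"""Exception types."""


class SpeechconnError(Exception):
    """Base class for all package errors."""


class ValidationError(SpeechconnError):
    """Malformed input: bad matrices, manifests, configs, or parameters."""
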