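"""Exception types with CLI exit-code semantics."""


class OctbandError(Exception):
    """Base class for package errors (CLI exit code 3)."""


class ValidationError(OctbandError, ValueError):
    """Invalid configuration or data; names the offending field (exit code 2)."""
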