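"""Exception hierarchy shared across the package."""


class MockbenchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MockbenchError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(MockbenchError):
    """A record violates a domain invariant."""


class ParameterError(MockbenchError):
    """An argument is outside its documented domain."""
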