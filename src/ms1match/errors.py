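"""Exception types shared across the package."""


class Ms1MatchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Ms1MatchError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class EmptyRunError(Ms1MatchError):
    """A run contains no (valid) MS1 features."""


class ParameterError(Ms1MatchError):
    """A parameter value is outside its documented domain."""
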