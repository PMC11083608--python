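"""Exception hierarchy shared by all hrvlab modules."""


class HrvLabError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HrvLabError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(HrvLabError, ValueError):
    """A text input could not be parsed; message names the offending line."""


class FormatError(HrvLabError, ValueError):
    """A file is syntactically readable but inconsistent with its declared layout."""
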