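"""Exception hierarchy shared across the toolkit."""


class SnailnetError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SnailnetError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(SnailnetError):
    """Input violated a documented precondition or invariant."""
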