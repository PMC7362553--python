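"""Exception hierarchy for boostgrn."""


class BoostgrnError(Exception):
    """Base class for all boostgrn errors."""


class FormatError(BoostgrnError):
    """A file's structure is malformed (ragged rows, bad header, ...)."""


class ParseError(FormatError):
    """A cell could not be parsed as the expected type."""


class ValidationError(BoostgrnError):
    """An in-memory object violates a contract or invariant."""
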