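"""Exception hierarchy shared across the package."""


class WquartetError(Exception):
    """Base class for all errors raised by wquartet."""


class NewickParseError(WquartetError):
    """Malformed Newick input.

    Carries ``offset`` (0-based character position, when known) so callers
    can point at the offending location.
    """

    def __init__(self, message, offset=None):
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)
        self.offset = offset


class ValidationError(WquartetError):
    """Structurally valid input that violates a data contract
    (duplicate labels, inconsistent leaf sets, taxon-index mismatch, ...)."""
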