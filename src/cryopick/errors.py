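"""Exception hierarchy shared by all pipeline stages."""


class CryopickError(Exception):
    """Base class for all cryopick errors."""


class FormatError(CryopickError):
    """A file could not be parsed as the declared format."""


class InvalidInputError(CryopickError):
    """Input data violates a precondition (empty stack, shape mismatch...)."""


class DegenerateInputError(InvalidInputError):
    """Input is degenerate for the operation (e.g. constant image)."""


class InvalidConfigError(CryopickError):
    """A configuration value is out of its valid range."""


class PlacementError(CryopickError):
    """Synthetic-scene shape placement failed under the separation constraint."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} shapes under the "
            "minimum-separation constraint"
        )
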