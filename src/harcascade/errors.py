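"""Exception hierarchy used across the package."""


class HarCascadeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(HarCascadeError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(HarCascadeError, ValueError):
    """Input data violate a precondition (empty, unordered, wrong shape...)."""


class InvalidLabelError(InvalidInputError):
    """An activity label outside the known taxonomy was encountered."""


class DegenerateOrientationError(InvalidInputError):
    """Tilt angles are undefined for a zero acceleration vector."""


class UntrainableModelError(HarCascadeError, ValueError):
    """A (sub-)model cannot be fitted, e.g. its dataset has a single class."""


class StratificationError(HarCascadeError, ValueError):
    """A class cannot be represented in both sides of a stratified split."""


class StreamParseError(InvalidInputError):
    """A malformed row in an acceleration stream file.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class InvalidStateError(HarCascadeError, RuntimeError):
    """The streaming loop was driven with an unusable model or state."""
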