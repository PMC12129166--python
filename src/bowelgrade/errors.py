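"""Exception types shared across the package."""


class BowelGradeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BowelGradeError, ValueError):
    """Input data violates a documented precondition."""


class InvalidArgumentError(BowelGradeError, ValueError):
    """A parameter value violates a documented precondition."""


class FormatError(BowelGradeError, ValueError):
    """A file does not conform to the expected schema."""


class UndefinedScoreError(BowelGradeError, ArithmeticError):
    """A score is mathematically undefined for this input (e.g. zero norm)."""
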