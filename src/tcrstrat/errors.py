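"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input failed a precondition (range, type, or shape)."""


class InfeasibleDilutionError(ValidationError):
    """A whole-cohort OR too small to arise from any positive stratum OR.

    Under the linear dilution model OR_all = f*OR_stratum + (1 - f), any
    OR_stratum > 0 yields OR_all > 1 - f; inverting an OR_all at or below
    that floor has no valid solution.
    """


class CatalogFormatError(ValidationError):
    """A polymorphism catalog stream contained malformed rows (strict mode)."""

    def __init__(self, message: str, lines: list[int]):
        super().__init__(message)
        self.lines = lines
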