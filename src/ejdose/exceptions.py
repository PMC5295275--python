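"""Exception hierarchy shared across the package."""


class EjdoseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EjdoseError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ValidationError(EjdoseError, ValueError):
    """A composite input (table, config, dataset) violates its invariants.

    Carries the full list of violations so callers can report every
    problem at once rather than failing on the first.
    """

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class SchemaError(EjdoseError, ValueError):
    """A file does not match the expected column schema."""


class ConfigError(EjdoseError, ValueError):
    """A run configuration is internally inconsistent."""
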