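"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems (2), data
validation problems (3), statistical failures (4).
"""


class ComorbidrxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ComorbidrxError):
    """A mapping resource, run configuration or argument is invalid."""


class SchemaError(ComorbidrxError):
    """An input file does not match the documented column schema."""


class RecordValidationError(ComorbidrxError):
    """A single record violates an invariant; carries the case id."""

    def __init__(self, case_id: str, message: str):
        self.case_id = case_id
        super().__init__(f"case {case_id!r}: {message}")


class StatisticalError(ComorbidrxError):
    """A model could not be fitted or a statistic is undefined."""


class SeparationError(StatisticalError):
    """Quasi-complete separation detected during logistic fitting."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(
            "separation detected (|coefficient| > 15 on the logit scale) "
            f"for term(s): {', '.join(self.terms)}"
        )


class InsufficientEventsError(StatisticalError):
    """Too few deaths in a stratum to support model fitting."""
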