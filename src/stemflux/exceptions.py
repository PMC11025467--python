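"""Error classes shared across the pipeline.

The split mirrors the exit-code contract of the command-line interface:
validation problems (bad input values, schema violations) are distinguished
from numeric/runtime failures so callers can map them to distinct exit codes.
"""


class StemfluxError(Exception):
    """Base class for all package errors."""


class ValidationError(StemfluxError, ValueError):
    """An input value violates a documented precondition (bad range, schema)."""


class DomainError(ValidationError):
    """An input is outside the mathematical domain of a formula."""


class InsufficientDataError(StemfluxError, ValueError):
    """Too few observations to perform the requested fit or statistic."""


class DegenerateFitError(StemfluxError, ValueError):
    """A regression design is singular (e.g. zero variance in the predictor)."""


class MissingInputError(StemfluxError, FileNotFoundError):
    """A required input file or prior stage product is absent."""
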