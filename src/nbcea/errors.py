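"""Exception hierarchy shared across the package.

Validation problems (bad input data or configuration) and computation
problems (a well-formed analysis that cannot be carried out) are kept
distinct so the command-line layer can map them to different exit codes.
"""


class NBCEAError(Exception):
    """Base class for all package errors."""


class ValidationError(NBCEAError):
    """Input data or configuration failed validation."""


class SchemaError(ValidationError):
    """A required column is missing or a table is structurally unusable."""


class RowError(ValidationError):
    """A specific row violates an invariant; the message names the row."""


class CohortError(ValidationError):
    """A cohort-level precondition failed (e.g. a single-arm cohort)."""


class ConfigError(ValidationError):
    """An analysis or generator configuration is inconsistent."""


class ComputationError(NBCEAError):
    """A stage of the analysis could not be computed (e.g. rank deficiency)."""
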