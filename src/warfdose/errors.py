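"""Exception hierarchy and CLI exit codes."""


class WarfdoseError(Exception):
    """Base class for all package errors."""


class SchemaError(WarfdoseError):
    """Input columns or a schema definition do not match expectations."""


class ValidationError(WarfdoseError):
    """Data values violate the schema or an operation's preconditions."""


class NumericError(WarfdoseError):
    """A numerical routine failed (non-finite objective, non-bracketing, ...)."""


class DegenerateModelError(WarfdoseError):
    """A model cannot be fitted: single-class labels, all basis pruned, ..."""


# CLI exit codes: 0 success, 2 validation, 3 numeric failure.
EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NUMERIC = 3
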