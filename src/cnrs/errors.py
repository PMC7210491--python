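"""Exception hierarchy shared across the pipeline stages."""


class CnrsError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(CnrsError):
    """Violation of the standardized data model (vocabulary, invariant, panel)."""


class ParseError(CnrsError):
    """Malformed input that the ingest stage cannot interpret."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class AuthorizationError(CnrsError):
    """Key-management operation attempted without a valid credential."""


class LeakError(CnrsError):
    """A raw identifier was detected where only pseudonymized keys are allowed."""


class InfeasibleSpecError(CnrsError):
    """A cohort specification demands counts its strata cannot accommodate."""
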