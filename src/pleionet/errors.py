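"""Exception hierarchy shared across the package."""


class PleionetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PleionetError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(PleionetError):
    """Parsed data violate an invariant (range, uniqueness, shape)."""


class ConfigError(PleionetError):
    """An option or configuration value is inconsistent or out of range."""


class DomainError(PleionetError):
    """An operation was asked about an entity outside its domain
    (e.g. a focal-gene query for a gene that is not a focal gene)."""


class PipelineStageError(PleionetError):
    """A pipeline stage failed; carries the stage name and a machine code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
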