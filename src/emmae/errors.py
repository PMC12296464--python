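"""Exception types shared across the pipeline."""


class EmmaeError(Exception):
    """Base class for all package errors."""


class FormatError(EmmaeError):
    """A file could not be parsed as the declared format."""


class UnsupportedInputError(EmmaeError):
    """The input is well-formed but outside the supported subset."""


class ContractViolationError(EmmaeError):
    """A caller broke a documented precondition."""


class TrainingError(EmmaeError):
    """Model training diverged or otherwise failed."""


class GenerationError(EmmaeError):
    """Synthetic-data generation could not satisfy its constraints."""
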