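"""Exception hierarchy shared across the package."""


class MechanotypesError(Exception):
    """Base class for all package errors."""


class SchemaError(MechanotypesError):
    """A required column is missing from an input table."""


class VocabularyError(MechanotypesError):
    """A substrate/feature/tissue label is outside the closed vocabulary."""


class MetadataError(MechanotypesError):
    """A cell line is absent from the accompanying metadata set."""


class ValidationError(MechanotypesError):
    """Rows violate feature invariants; carries the offending row numbers."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class DuplicateKeyError(MechanotypesError):
    """Duplicate (cell_line, substrate, feature, cell_id) keys."""


class InsufficientDataError(MechanotypesError):
    """Not enough samples to perform an operation."""


class InputError(MechanotypesError):
    """Structurally invalid input (non-monotone axis, mixed features, ...)."""


class ConfigurationError(MechanotypesError):
    """Invalid generator or pipeline configuration."""


class DetectionError(MechanotypesError):
    """Contact-point detection found no admissible split."""


class DegenerateDataError(MechanotypesError):
    """Input is degenerate for the requested estimate (e.g. constant sample)."""


class FetchError(MechanotypesError):
    """Downloading or checksumming external study data failed."""


class MappingError(MechanotypesError):
    """A column-mapping file does not cover a required schema column."""


class StageError(MechanotypesError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
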