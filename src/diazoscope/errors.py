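"""Exception hierarchy shared across the pipeline stages."""


class DiazoscopeError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(DiazoscopeError):
    """Annotation or sample coordinates out of bounds / out of range."""


class AnnotationError(DiazoscopeError):
    """Malformed gene annotation (frame, strand, missing reference)."""


class AbsentMarkerError(DiazoscopeError):
    """A required marker gene is absent from the genome."""


class ConfigError(DiazoscopeError):
    """Invalid configuration value or range."""


class MetadataError(DiazoscopeError):
    """Missing or inconsistent sample metadata."""


class MergeConflictError(DiazoscopeError):
    """Samples with incompatible metadata cannot be merged."""


class ConsistencyError(DiazoscopeError):
    """Internal cross-table inconsistency (e.g. count without a length)."""


class InputError(DiazoscopeError):
    """Malformed input data (FASTQ records, distance matrices, ...)."""
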