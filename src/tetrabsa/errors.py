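"""Exception types shared across the pipeline stages."""


class TetrabsaError(ValueError):
    """Base class for all pipeline errors."""


class SizingError(TetrabsaError):
    """A contig is too short to host the requested gene models."""


class PlacementError(TetrabsaError):
    """More variant sites requested than candidate positions available."""


class CoordinateError(TetrabsaError):
    """A position falls outside the reference sequence bounds."""


class SchemaError(TetrabsaError):
    """A record is missing a required attribute or has mismatched shapes."""


class ModelIntegrityError(TetrabsaError):
    """A gene model violates its structural contract (e.g. CDS length % 3 != 0)."""


class ReferenceMismatchError(TetrabsaError):
    """A variant's stated reference allele disagrees with the reference sequence."""


class PipelineOrderError(TetrabsaError):
    """A stage was invoked before an upstream product it requires exists."""


class ConfigurationError(TetrabsaError):
    """A run configuration is invalid (e.g. empty curated pathway set)."""
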