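"""Exception hierarchy for the discstoich pipeline."""


class DiscStoichError(Exception):
    """Base class for all pipeline errors."""


class UnitMismatchError(DiscStoichError):
    """Spectrum matches carry inconsistent mass-error units (Da vs ppm)."""


class DuplicateRecordError(DiscStoichError):
    """The same accession appears twice within one sample run."""


class ReferenceAccessionError(DiscStoichError):
    """Relative-SAF reference is missing or has zero SAF in a replicate."""


class DegenerateReplicateError(DiscStoichError):
    """All SAF values are zero in a replicate; NSAF is undefined."""


class StoichiometryUndefinedError(DiscStoichError):
    """Combined NSAF of the reference (FADD) category is zero."""


class DegeneracyError(DiscStoichError):
    """Too few or collinear points for a rigid-body superposition."""


class InterfaceNotSimilarError(DiscStoichError):
    """Interface superposition RMSD exceeds the acceptance threshold."""


class DegenerateTruthError(DiscStoichError):
    """Synthetic ground truth has zero total sampling weight."""


class TableParseError(DiscStoichError):
    """A tabular input failed schema or value validation."""

    def __init__(self, message: str, row: int | None = None,
                 column: str | None = None) -> None:
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column '{column}'")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.row = row
        self.column = column


class ConfigError(DiscStoichError):
    """Pipeline configuration is incomplete or inconsistent."""


class PipelineStageError(DiscStoichError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
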