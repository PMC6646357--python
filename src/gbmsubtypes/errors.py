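"""Exception hierarchy for the gbmsubtypes package."""


class GbmSubtypesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GbmSubtypesError):
    """Invalid simulation or pipeline configuration."""


class CohortValidationError(GbmSubtypesError):
    """A cohort violates its structural invariants."""


class UndefinedCorrelationError(GbmSubtypesError):
    """Pearson correlation undefined (zero variance or too few points)."""


class ScoringError(GbmSubtypesError):
    """ssGSEA scoring cannot be performed (overlap/complement undefined)."""


class DegenerateCohortError(GbmSubtypesError):
    """Standardization impossible: too few samples or zero score spread."""


class EstimationError(GbmSubtypesError):
    """A model fit failed (non-convergence, separation, degenerate groups)."""


class AlignmentError(GbmSubtypesError):
    """Sample identifiers of two tables do not align."""


class EmptyScanError(GbmSubtypesError):
    """A cutoff scan produced no valid dichotomization."""


class FormatError(GbmSubtypesError):
    """A file does not conform to its declared format (GCT/GMT/TSV)."""


class StageError(GbmSubtypesError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
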