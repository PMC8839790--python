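"""Exception hierarchy shared across the package."""


class AquahoneyError(Exception):
    """Base class for package errors."""


class SchemaError(AquahoneyError, ValueError):
    """A required column or field is missing or malformed."""


class SpectraValidationError(AquahoneyError, ValueError):
    """Spectra or metadata violate a structural invariant."""


class RangeError(AquahoneyError, ValueError):
    """A wavelength range selection is empty or ill-formed."""


class DimensionError(AquahoneyError, ValueError):
    """Matrix dimensions are incompatible with the requested operation."""


class DegenerateRowError(AquahoneyError, ValueError):
    """A spectrum row is degenerate for the requested transform (zero
    variance for SNV, zero regression slope for MSC)."""


class FoldError(AquahoneyError, ValueError):
    """Cross-validation folds cannot be constructed."""


class ClassSupportError(AquahoneyError, ValueError):
    """A class has too few training samples."""


class DegenerateTargetError(AquahoneyError, ValueError):
    """The regression target is constant or undefined."""


class GroupError(AquahoneyError, ValueError):
    """A required group (e.g. the untreated control) is absent."""


class SelectionError(AquahoneyError, ValueError):
    """Wavelength-vote selection produced no usable coordinates."""


class DegenerateCoordinateError(AquahoneyError, ValueError):
    """An aquagram coordinate has zero variance across the comparison set."""


class RenderError(AquahoneyError, ValueError):
    """A plot cannot be rendered from the given object."""


class SupportError(AquahoneyError, ValueError):
    """A statistical test has insufficient per-group sample size."""


class DesignError(AquahoneyError, ValueError):
    """The experimental design table is incomplete or illegal."""


class MatrixError(AquahoneyError, ValueError):
    """A pairwise comparison matrix is incomplete."""


class ConfigError(AquahoneyError, ValueError):
    """A run configuration failed schema validation."""
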