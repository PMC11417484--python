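"""Exception hierarchy shared across the package."""


class CardiomassError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CardiomassError):
    """Phantom or anatomy geometry is invalid (annulus outside grid, zero wall, ...)."""


class ConfigurationError(CardiomassError):
    """A run/spec configuration violates its invariants."""


class ValidationError(CardiomassError):
    """Input data fails a structural contract (unknown label, bad header, ...)."""


class DataError(CardiomassError):
    """Tabular data is inconsistent (e.g. event date without baseline date)."""


class EmptyAnatomyError(CardiomassError):
    """A stack contains no myocardial pixels to quantify."""


class InsufficientCoverageError(CardiomassError):
    """Fewer myocardium-containing slices than the apical selection needs."""


class NoSeptumError(CardiomassError):
    """No slice shows RV contact, so septal mass is undefined."""


class DegenerateContactError(CardiomassError):
    """RV contact arc spans >= 180 degrees; insertion points are ill-defined."""


class FitDiagnosticError(CardiomassError):
    """A model fit failed: non-convergence, separation or collinearity."""


class AlleleMismatchError(CardiomassError):
    """A PRS weight's effect allele matches neither ref nor alt of the panel."""
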