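"""Exception types shared across the package."""


class MitohetError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MitohetError, ValueError):
    """A position lies outside the circular mitochondrial coordinate system."""


class LabelParseError(MitohetError, ValueError):
    """A variant label string does not match the supported nomenclature."""


class AnnotationError(MitohetError, LookupError):
    """A position or region name cannot be resolved against the annotation."""


class InsufficientCoverageError(MitohetError, ValueError):
    """A per-site quantity was requested at zero sequencing depth."""


class InsufficientDataError(MitohetError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(MitohetError, ValueError):
    """Correlation requested on a constant (zero-variance) vector."""


class ConfigError(MitohetError, ValueError):
    """A filter configuration references unknown options."""


class DesignError(MitohetError, ValueError):
    """A simulation design is internally inconsistent or infeasible."""
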