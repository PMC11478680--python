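"""Exception hierarchy for chlorospec.

All package errors derive from :class:`ChlorospecError` so callers can
catch everything with one clause while tests discriminate precisely.
"""


class ChlorospecError(Exception):
    """Base class for all chlorospec errors."""


class SchemaError(ChlorospecError):
    """A required metadata column is missing or malformed."""


class GridError(ChlorospecError):
    """The wavelength grid is absent, non-uniform, or non-monotone."""


class SpectraValidationError(ChlorospecError):
    """Reflectance values violate the raw-spectrum contract."""


class TransformError(ChlorospecError):
    """A spectral transform hit a domain violation or degenerate row."""


class RegistryError(ChlorospecError):
    """An unknown transform or index name was requested."""


class IndexComputationError(ChlorospecError):
    """A vegetation index could not be computed (e.g. zero denominator)."""


class ParameterError(ChlorospecError):
    """An operation received an out-of-range parameter."""


class ShapeError(ChlorospecError):
    """Mismatched array dimensions between predictors and response."""


class FitError(ChlorospecError):
    """A regression fit failed (rank deficiency, degenerate design)."""


class ConfigError(ChlorospecError):
    """A generator or pipeline configuration violates its invariants."""


class ComparabilityError(ChlorospecError):
    """Two accuracy reports cannot be compared (different folds/seeds)."""


class EvaluationError(ChlorospecError):
    """A hold-out evaluation could not be stratified as required."""
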