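"""Exception hierarchy shared across the package."""


class SinumetryError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SinumetryError, ValueError):
    """An input value violates a domain constraint (sign, range, vocabulary)."""


class ParseError(SinumetryError, ValueError):
    """A file could not be parsed; the message names the offending row."""


class DuplicateRecordError(SinumetryError, ValueError):
    """The same (patient, date, structure, label) appears more than once."""


class InsufficientDataError(SinumetryError, ValueError):
    """Too few non-missing values to compute the requested statistic."""


class DegenerateDesignError(SinumetryError, ValueError):
    """A regression design with no spread in the predictor."""


class GeometryError(SinumetryError, ValueError):
    """A phantom cavity does not fit inside the voxel grid."""


class SeedOutsideCavityError(SinumetryError, ValueError):
    """The segmentation seed voxel is above the HU threshold."""


class DesignError(SinumetryError, ValueError):
    """A reliability design that cannot identify the requested components."""
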