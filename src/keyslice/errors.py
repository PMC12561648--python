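"""Exception hierarchy shared across the package."""


class KeySliceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KeySliceError):
    """A file could not be parsed in the requested format."""


class SeriesError(KeySliceError):
    """A DICOM directory is empty or mixes acquisition series."""


class ShapeError(KeySliceError):
    """An array does not have the shape an operation requires."""


class ParameterError(KeySliceError):
    """A numeric parameter is outside its valid range."""


class InputError(KeySliceError):
    """Input data is empty or otherwise degenerate."""


class ConfigError(KeySliceError):
    """A configuration mapping contains unknown or malformed entries."""


class CalibrationError(KeySliceError):
    """Threshold calibration received non-informative scores."""


class MissingStudyError(KeySliceError):
    """An annotation refers to a study with no matching volume or labels."""


class SpecError(KeySliceError):
    """A synthetic-data specification is internally inconsistent."""


class TrainingError(KeySliceError):
    """Training diverged (non-finite loss)."""
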