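"""Exception taxonomy shared across the pipeline.

Exit-code contract (used by the CLI):
    2 -- validation failure (bad inputs, bad parameters, schema problems)
    3 -- I/O failure (unreadable/unwritable files)
    4 -- computation invariant breach
"""


class PipelineError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 4


class ValidationError(PipelineError):
    """Invalid input data or parameters."""

    exit_code = 2


class SpecError(ValidationError):
    """Invalid synthetic-data or run specification."""


class SchemaError(ValidationError):
    """Tabular input missing required columns or containing unknown categories."""


class ParseError(ValidationError):
    """A cell could not be parsed; message carries the row number."""


class FormatError(ValidationError):
    """Image file has the wrong mode/bit depth; message names the property."""


class DimensionError(ValidationError):
    """Raster shapes disagree."""


class EmptyRoiError(ValidationError):
    """ROI mask contains no true pixel."""


class CardinalityError(ValidationError):
    """Wrong number of values for an aggregation."""


class DuplicationError(ValidationError):
    """Conflicting duplicate measurement rows."""


class IncompleteError(ValidationError):
    """A required thrombus part is missing; message names it."""


class SeriesLengthError(ValidationError):
    """Series too short for the requested fit."""


class SeriesGapError(ValidationError):
    """Series days are not consecutive."""


class WindowError(ValidationError):
    """Requested detection window falls outside the series."""


class IOFailure(PipelineError):
    """File could not be read or written."""

    exit_code = 3


class InvariantError(PipelineError):
    """A computation invariant was violated."""

    exit_code = 4


class DegenerateSectionError(InvariantError):
    """All in-ROI pixels are background: no tissue to quantify."""
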