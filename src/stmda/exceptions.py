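"""Exception hierarchy for stMDA."""


class StmdaError(Exception):
    """Base class for all stMDA errors."""


class FormatError(StmdaError, ValueError):
    """A required input file is missing or malformed."""


class ParseError(FormatError):
    """A cell of a tabular input could not be parsed."""


class AlignmentError(StmdaError, ValueError):
    """Spot identifiers disagree between input files."""


class ParameterError(StmdaError, ValueError):
    """An argument is outside its valid range."""


class ModalityAbsentError(StmdaError, ValueError):
    """An operation requires a modality the dataset does not carry."""


class ShapeError(StmdaError, ValueError):
    """Array dimensions are inconsistent."""
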