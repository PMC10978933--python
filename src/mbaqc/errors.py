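"""Exception hierarchy shared across the QC modules."""


class MbaQcError(Exception):
    """Base class for all package errors."""


class ParseError(MbaQcError):
    """A plate file could not be parsed into the expected structure."""


class UnsupportedPlateLayoutError(ParseError):
    """File holds more than one plate run or a non-96-well format."""


class MissingBlockError(ParseError):
    """A required data block is absent from an xPONENT-style CSV."""


class MissingSheetError(ParseError):
    """A required sheet ("attribute") is absent from a BPM-style workbook."""


class DuplicateBatchError(MbaQcError):
    """Two inputs contribute the same (batch, well, antigen) records."""


class EmptyDatasetError(MbaQcError):
    """An operation that requires data received an empty dataset."""


class UnknownAntigenError(MbaQcError):
    """Requested antigen is not present on the plate/dataset."""


class NoBackgroundWellError(MbaQcError):
    """MFI flagging requested on a plate without background wells."""


class InsufficientDataError(MbaQcError):
    """A control series is too short for the requested chart method."""


class EmptySeriesError(MbaQcError):
    """The requested control-antigen pair has no data anywhere."""
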