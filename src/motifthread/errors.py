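"""Exception hierarchy."""


class MotifThreadError(Exception):
    """Base class for all package errors."""


class StructureFormatError(MotifThreadError):
    """Unparseable or malformed structure input."""


class CurationError(MotifThreadError):
    """A complex fails one of the curation filters."""


class GeometryError(MotifThreadError):
    """Degenerate geometry (collinear fit points, bad contact pattern...)."""


class StructureError(MotifThreadError):
    """A structure is missing atoms required by an operation."""


class PotentialError(MotifThreadError):
    """Training or scoring cannot proceed (empty input, unknown types...)."""


class MotifError(MotifThreadError):
    """Degenerate score tables, malformed PWMs, format errors."""


class ComparisonError(MotifThreadError):
    """Motif comparison / calibration failures."""


class ScanError(MotifThreadError):
    """Promoter extraction or scanning failures."""
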