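"""Exception hierarchy for doseqa.

All package-specific failures derive from :class:`DoseQAError` so callers can
catch one base class at the CLI boundary.
"""


class DoseQAError(Exception):
    """Base class for all doseqa errors."""


class FormatError(DoseQAError):
    """A file is not in the expected format (e.g. not an RTDOSE object)."""


class UnsupportedGeometryError(DoseQAError):
    """Geometry is valid DICOM/NRRD but not supported (e.g. tilted grids)."""


class GeometryError(DoseQAError):
    """Inconsistent or degenerate grid geometry."""


class EmptyGridError(DoseQAError):
    """A dose grid carries no usable signal (e.g. all-zero maximum)."""


class EmptyStatisticsError(DoseQAError):
    """A statistic was requested over an empty collection of values."""


class DegenerateTargetError(DoseQAError):
    """The target structure cannot support the requested metric."""


class ParameterError(DoseQAError):
    """A numeric parameter is outside its valid domain."""


class DataError(DoseQAError):
    """Cohort data is missing a required metric or is malformed."""


class SizeError(DoseQAError):
    """An input exceeds a hard size limit (e.g. brute-force oracle grids)."""


class ConfigurationError(DoseQAError):
    """A study configuration is inconsistent or incomplete."""
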