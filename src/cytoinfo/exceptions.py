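"""Exception hierarchy.

All errors raised by cytoinfo derive from :class:`CytoInfoError` so callers
can catch the package's failures with one clause; the subclasses mirror the
distinct failure modes of the analysis (bad parameters, malformed input
files, degenerate data).
"""


class CytoInfoError(Exception):
    """Base class for all cytoinfo errors."""


class ParameterError(CytoInfoError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(CytoInfoError, ValueError):
    """Unknown or unparseable file format."""


class SchemaError(CytoInfoError, ValueError):
    """Required columns or channels are missing."""


class EmptyDataError(CytoInfoError, ValueError):
    """No usable events remain after loading/filtering."""


class DegenerateDataError(CytoInfoError, ValueError):
    """Data are degenerate for the requested computation.

    Raised e.g. for zero-variance samples in density estimation or
    all-zero responses in normalization.
    """
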