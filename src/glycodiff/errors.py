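"""Exception hierarchy for glycodiff.

All errors raised on purpose by the package derive from :class:`GlycodiffError`
so callers can catch pipeline failures without masking programming errors.
"""


class GlycodiffError(Exception):
    """Base class for all glycodiff errors."""


class InvalidParameterError(GlycodiffError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class ParseError(GlycodiffError, ValueError):
    """An input file or field could not be parsed; message names the location."""


class CapacityError(GlycodiffError):
    """A simulation request exceeds what the generated proteome can host."""


class MappingError(GlycodiffError):
    """A peptide could not be located on its declared protein."""


class AmbiguousLocationError(MappingError):
    """A peptide occurs at more than one position in the protein."""


class InconsistencyError(GlycodiffError):
    """Modification annotations contradict the peptide sequence."""


class InsufficientDataError(GlycodiffError):
    """Too few observations to estimate a distribution summary."""


class NormalizationError(GlycodiffError):
    """A channel has no usable values for normalization."""


class ConfigurationError(GlycodiffError):
    """Mismatched design/null-model/table combination."""
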