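"""Exception hierarchy for kleevec.

All package errors derive from :class:`KleevecError` so callers can catch
broadly; specific subclasses identify the stage that failed.
"""


class KleevecError(Exception):
    """Base class for all kleevec errors."""


class AlignmentError(KleevecError):
    """Malformed alignment input (unequal lengths, empty file, ...)."""


class ManifestError(KleevecError):
    """Group manifest does not cover the alignment or is inconsistent."""


class EncodingError(KleevecError):
    """A character cannot be mapped to a probability quartet."""


class ShapeError(KleevecError):
    """Vector/matrix dimensions are inconsistent."""


class MaskError(KleevecError):
    """A site mask does not match the data, or removes everything."""


class EmptyDatasetError(KleevecError):
    """A filter or split removed every sequence."""


class ConfigurationError(KleevecError):
    """Invalid run configuration (e.g. no admissible groups)."""


class DegenerateGroupError(KleevecError):
    """The indicator eigenproblem has no positive leading eigenvalue."""


class ConservationError(KleevecError):
    """Quartet sums of an indicator vector are not mutually equal,
    so the probability normalization is undefined."""


class TreeError(KleevecError):
    """Invalid distance matrix or tree operation."""
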