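"""Exception hierarchy for the curation pipeline.

Every error that removes an entry from the batch (rather than aborting it)
is a ``CryosetError`` subclass so pipeline stages can catch one type,
tally the entry in the curation report, and move on.
"""


class CryosetError(Exception):
    """Base class for all package errors."""


class RetrievalError(CryosetError):
    """Network retrieval failed after bounded retries."""


class MetadataParseError(CryosetError):
    """A metadata record or cache file could not be parsed."""


class MapFormatError(CryosetError):
    """An MRC file is malformed or internally inconsistent."""


class ModelFormatError(CryosetError):
    """An atomic-model file could not be parsed."""


class EmptyModelError(ModelFormatError):
    """A model file contains zero atoms."""


class NormalizationError(CryosetError):
    """Adaptive contour-anchored normalization cannot be performed.

    Raised when the contour sits at/above the map maximum (nothing to
    retain) or below the map's own anchor percentile (the closed-form
    retained count exceeds the voxel count), or when the retained value
    range is flat.  Pipeline stages count these as "unsuccessful
    normalization" and drop the entry.
    """


class SimilarityUndefinedError(CryosetError):
    """Cross-reference similarity requested for an empty accession set."""


class DegenerateOutputError(CryosetError):
    """Resampling would produce a zero-size axis."""


class StageOrderingError(CryosetError):
    """A pipeline stage was run before its prerequisites produced output."""


class UsageError(CryosetError, ValueError):
    """Invalid argument combination supplied by the caller."""
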