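"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`RangexpandError`, so callers can catch the package's failures
without masking programming errors.
"""


class RangexpandError(Exception):
    """Base class for all rangexpand errors."""


class ParseError(RangexpandError):
    """A file could not be parsed; the message names the offending line."""


class PloidyError(ParseError):
    """A genotype record does not describe a diploid sample."""


class LookupError_(RangexpandError):
    """A sample, population or label was not found where required."""


class ConfigurationError(RangexpandError):
    """An inconsistent simulator or analysis configuration."""


class SamplingError(RangexpandError):
    """A sampling request cannot be satisfied (empty deme, too few haplotypes)."""


class CoverageError(RangexpandError):
    """Ancestry tracts do not cover required variant positions."""


class DatingError(RangexpandError):
    """Admixture dating is impossible (no non-target tracts)."""


class AlignmentError(RangexpandError):
    """Two labelled objects do not share the same labels/ordering."""


class DegenerateInputError(RangexpandError):
    """Too few observations for the requested statistic."""


class RarefactionError(RangexpandError):
    """Rarefaction depth exceeds the available haplotypes."""


class ConnectivityError(RangexpandError):
    """A graph operation found the input disconnected."""


class EmptyDatasetError(RangexpandError):
    """A filtering step removed every sample."""
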