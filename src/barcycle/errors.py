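"""Exception hierarchy for barcycle.

All library errors derive from :class:`BarcycleError` so callers can catch
one type at the pipeline boundary.
"""


class BarcycleError(Exception):
    """Base class for all barcycle errors."""


class InvalidParameterError(BarcycleError, ValueError):
    """A parameter is outside its documented domain (e.g. k > sequence length)."""


class InvalidAlphabetError(BarcycleError, ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class EmptyInputError(BarcycleError, ValueError):
    """An input stream or file yielded no usable records."""


class NotFoundError(BarcycleError, KeyError):
    """A requested k-mer has no postings in the index."""


class InvalidComparisonError(BarcycleError, ValueError):
    """Two indices built with different k were compared."""


class DegenerateInputError(BarcycleError, ValueError):
    """Too few data points for the requested smoothing window."""


class NoKneeError(BarcycleError, ValueError):
    """The capacity curve has no interior inflection (e.g. all values equal)."""


class FastqParseError(BarcycleError, ValueError):
    """A FASTQ record could not be parsed."""
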