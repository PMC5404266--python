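"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`NppsError`
so callers (and the CLI) can catch one type and exit cleanly.
"""


class NppsError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(NppsError):
    """The input file is not parseable as FASTA."""


class ValidationError(NppsError):
    """A sequence record violates the alphabet or length contract."""


class ContractError(NppsError):
    """Caller broke an interface precondition (shape/row-count mismatch, ...)."""


class ParameterError(NppsError):
    """An out-of-range or inconsistent parameter value (e.g. ξ > l - 2)."""


class FitError(NppsError):
    """Profile fitting is impossible (e.g. empty training class)."""


class TrainingError(NppsError):
    """SVM training is impossible (single-class labels, non-finite input)."""


class ModelFormatError(NppsError):
    """A model file could not be read as a saved model."""


class ChecksumMismatchError(NppsError):
    """A model's embedded encoder checksum does not match the supplied profiles."""
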