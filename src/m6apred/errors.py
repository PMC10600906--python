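"""Exception hierarchy shared across the package.

Every raised error derives from :class:`M6aPredError` so callers can catch
domain failures without masking programming errors.
"""


class M6aPredError(Exception):
    """Base class for all package errors."""


class EmptyInputError(M6aPredError):
    """Input file or record list contains no usable entries."""


class AlphabetError(M6aPredError):
    """A sequence mixes T and U, or alphabets are inconsistent."""


class InvalidCharacterError(M6aPredError):
    """A sequence contains a character outside the canonical alphabet."""

    def __init__(self, record_id: str, char: str):
        self.record_id = record_id
        self.char = char
        super().__init__(
            f"record {record_id!r}: invalid character {char!r} "
            "(only A, C, G, T, U accepted)"
        )


class HeterogeneousLengthError(M6aPredError):
    """Records in one dataset do not share a common length."""


class CenterUndefinedError(M6aPredError):
    """Center-A check requested on an even-length sequence set."""


class CenterViolationError(M6aPredError):
    """One or more records lack adenine at the center position."""

    def __init__(self, record_ids):
        self.record_ids = list(record_ids)
        shown = ", ".join(self.record_ids[:10])
        more = "" if len(self.record_ids) <= 10 else f" (+{len(self.record_ids) - 10} more)"
        super().__init__(f"non-A center base in records: {shown}{more}")


class MissingClassError(M6aPredError):
    """An operation requiring both classes saw only one."""


class SequenceTooShortError(M6aPredError):
    """Sequence shorter than the encoder parameter allows."""


class InvalidFeatureError(M6aPredError):
    """Feature matrix contains NaN or infinite values."""


class DimensionError(M6aPredError):
    """Vector/matrix shapes are incompatible."""


class StratificationError(M6aPredError):
    """A class has fewer members than the requested fold count."""


class UndefinedAUCError(M6aPredError):
    """AUC requested with only one class present."""


class EmptyEvaluationError(M6aPredError):
    """Metrics requested on an empty confusion table."""


class UnknownModelError(M6aPredError):
    """Unrecognized classifier family name."""


class SearchFailedError(M6aPredError):
    """Every sampled hyperparameter point failed to fit."""


class ConfigError(M6aPredError):
    """Invalid run or fixture configuration."""
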