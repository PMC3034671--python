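"""Exception hierarchy for htsqc."""


class HtsqcError(Exception):
    """Base class for all htsqc errors."""


class FormatError(HtsqcError):
    """Malformed or inconsistent plate data on input/output."""


class UndefinedStatisticError(HtsqcError):
    """A statistic was requested on data that cannot support it
    (e.g. fewer than two valid wells, zero variance)."""


class DegenerateDataError(HtsqcError):
    """Data degenerate for the requested transform (e.g. zero MAD,
    constant series after detrending)."""


class PairingError(HtsqcError):
    """Replicate pairing is missing or not a perfect matching."""


class EvaluationError(HtsqcError):
    """Detection output does not cover the ground-truth lines."""
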