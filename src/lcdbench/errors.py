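"""Exception hierarchy shared across the benchmark modules."""


class LcdBenchError(Exception):
    """Base class for all lcdbench errors."""


class InvalidConditionError(LcdBenchError):
    """Acquisition condition is physically impossible (e.g. non-positive mAs)."""


class PlacementError(LcdBenchError):
    """A low-contrast object does not fit inside the patch."""


class InvalidDesignError(LcdBenchError):
    """A dataset design request is inconsistent (odd counts, empty grids...)."""


class ArchitectureError(LcdBenchError):
    """Detector configuration cannot be realized as a network."""


class DegenerateTrainingError(LcdBenchError):
    """Training data contains a single class."""


class InputError(LcdBenchError):
    """Inputs violate an operation's contract (geometry mismatch, bad class index...)."""


class UndefinedROCError(LcdBenchError):
    """ROC/AUC requested for data with a single class."""
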