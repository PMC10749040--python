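"""Package-wide exception hierarchy."""


class RacemixError(Exception):
    """Base class for all racemix errors."""


class InsufficientDataError(RacemixError):
    """Raised when an operation is given too few records to proceed."""


class SingularDesignError(RacemixError):
    """Raised when a model design matrix is rank deficient."""


class ConvergenceError(RacemixError):
    """Raised when an iterative fit fails to converge."""
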