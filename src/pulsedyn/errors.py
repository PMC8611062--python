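"""Exception hierarchy for pulsedyn."""


class PulsedynError(Exception):
    """Base class for all pulsedyn errors."""


class InputError(PulsedynError):
    """Raised when raw input data violates its contract (e.g. probability outside [0,1])."""


class EmptyInputError(InputError):
    """Raised when an input table contains no usable rows."""


class ParameterError(PulsedynError):
    """Raised when a function argument is outside its admissible range."""


class InvalidEpisodeError(PulsedynError):
    """Raised when a smoking episode violates the four-puffs-in-five-minutes contract."""


class EmptyDatasetError(PulsedynError):
    """Raised when chunking retains no chunk of sufficient length."""


class CannotSplitError(PulsedynError):
    """Raised when a dataset has too few chunks to split into modeling/validation sides."""


class InfeasibleModelError(PulsedynError):
    """Raised when the identification program is infeasible on the given pole grid."""


class InternalConsistencyError(PulsedynError):
    """Raised when an assembled response is not real despite conjugate-symmetric coefficients."""


class UnclassifiableResponseError(PulsedynError):
    """Raised when a pulse response is identically zero and carries no shape to classify."""


class GenerationError(PulsedynError):
    """Raised when the synthetic generator cannot achieve the requested threshold margin."""
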