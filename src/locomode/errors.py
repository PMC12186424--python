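"""Exception hierarchy shared across the pipeline."""


class LocomodeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LocomodeError):
    """An in-memory object violates its invariants."""


class FormatError(LocomodeError):
    """An on-disk artifact does not match the documented layout."""


class ConfigurationError(LocomodeError):
    """A parameter combination is unusable (e.g. filter edge at/above Nyquist)."""


class StreamingError(LocomodeError):
    """A streaming chunk cannot be processed (e.g. contains NaN)."""


class EdgeEventError(LocomodeError):
    """A gait event lies too close to the recording edge for window extraction."""


class UnresolvableMarkerError(LocomodeError):
    """A transition marker has no eligible gait event at or after it."""


class MarkerCollisionError(LocomodeError):
    """Two transition markers realigned to the same gait event."""


class TrainingError(LocomodeError):
    """A classifier (or one cell of the bank) cannot be trained."""


class DataIntegrityError(LocomodeError):
    """Training data contradict the transition-legality map."""


class NumericalError(LocomodeError):
    """A linear-algebra step failed; usually fixed by shrinkage > 0."""


class CompatibilityError(LocomodeError):
    """A trained model does not match the session montage / feature layout."""


class ContractError(LocomodeError):
    """A call violated an interface contract (e.g. wrong window count)."""
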