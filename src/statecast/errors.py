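"""Exception hierarchy shared across the pipeline stages."""


class StatecastError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StatecastError, ValueError):
    """A configuration object failed validation before any computation."""


class InputError(StatecastError, ValueError):
    """Malformed in-memory input (wrong values, lengths, or dtypes)."""


class DataError(StatecastError, ValueError):
    """A cohort-level data problem, e.g. nothing survives filtering."""


class LengthError(InputError):
    """An individual's series is too short for the requested gap."""


class SplitError(StatecastError, ValueError):
    """A chronological split would leave train or test empty."""


class DegenerateTrainingError(StatecastError, RuntimeError):
    """Training targets contain a single class; the backend cannot fit."""


class SingleClassError(InputError):
    """AUC requested on a truth vector with only one class present."""


class BackendError(StatecastError, RuntimeError):
    """A classifier backend failed; carries individual/config context."""


class ExperimentError(StatecastError, RuntimeError):
    """Every individual failed for every configuration."""


class IncompleteExperimentError(StatecastError, ValueError):
    """The metrics table is missing a (model, gap, mode) cell."""
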