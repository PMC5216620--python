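"""Exception hierarchy for the connage pipeline."""


class ConnageError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ConnageError):
    """A configuration value is out of range or internally inconsistent."""


class InsufficientDataError(ConnageError):
    """Too few time points / subjects for the requested operation."""


class InvalidBandError(ConnageError):
    """Band-pass edges outside (0, Nyquist) or inverted."""


class EmptySeedError(ConnageError):
    """Seed definition resolves to no usable nodes."""


class DegenerateSeedError(ConnageError):
    """Seed signal has zero variance."""


class EmptyFeatureError(ConnageError):
    """No features survive selection / definition."""


class UninformativeFeaturesError(ConnageError):
    """All candidate features are constant."""


class ClassSizeError(ConnageError):
    """A class is too small for leave-one-out classification."""


class StageError(ConnageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
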