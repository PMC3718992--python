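"""Package-wide exception and warning types."""


class ValidationError(ValueError):
    """Input values violate a documented invariant (negative dose, w0 <= 0, ...)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (oral dose without absorption rate, missing arm, ...)."""


class NonIdentifiableError(ConfigurationError):
    """The requested fit cannot be identified from the arms present in the dataset."""


class WindowTooShortError(RuntimeError):
    """A growth curve never reaches the requested reference weight inside its window.

    Carries ``required_extension`` (days), a linear-extrapolation estimate of how much
    longer the simulation window would need to be.
    """

    def __init__(self, message: str, required_extension: float | None = None):
        super().__init__(message)
        self.required_extension = required_extension


class ModelValidityWarning(UserWarning):
    """The model was evaluated in a regime the underlying assumptions do not cover.

    Emitted e.g. when a strongly negative interaction parameter makes the net kill
    rate on proliferating cells negative (drug exposure would *create* cells).
    """
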