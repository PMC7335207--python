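"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A schedule or model configuration is internally inconsistent."""


class ScheduleError(RuntimeError):
    """Constrained schedule construction failed within the retry budget."""


class FitError(RuntimeError):
    """Model fitting could not be carried out on the given data."""
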