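"""Exception hierarchy shared across the package."""


class InvalidInputError(ValueError):
    """An image, map, or batch violates a documented precondition."""


class ConfigurationError(ValueError):
    """A config value is inconsistent (bad key, bad type, bad range)."""


class TrainingDivergedError(RuntimeError):
    """A loss became non-finite during adversarial training."""
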