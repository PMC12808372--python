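"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration record violates its documented constraints.

    The message always names the offending field so that callers can fix
    declarative specs (SynthSpec, ModelConfig, TrainPlan, ...) directly.
    """


class GeometryError(ValueError):
    """Array geometry (channels / samples / classes) is incompatible."""
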