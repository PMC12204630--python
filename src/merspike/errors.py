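"""Exception types used across the package."""


class InvalidParameterError(ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable information
    (all-zero trace, constant waveform, ...)."""


class InsufficientSpikesError(ValueError):
    """Too few spikes to estimate a quantity (e.g. a projection profile
    needs at least 5 spikes)."""


class NumericalError(RuntimeError):
    """A numerical procedure produced non-finite intermediate values."""
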