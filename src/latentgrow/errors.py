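"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data (out-of-bounds click, empty mask, ...)."""


class ConfigurationError(ValueError):
    """Weights, spec, or config inconsistent with each other."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate (constant image, <2 samples)."""
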