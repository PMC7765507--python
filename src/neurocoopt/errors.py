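"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A required column, marker gene or config key is missing or invalid."""


class ValidationError(ValueError):
    """Input data violate a documented invariant (e.g. non-positive survival times)."""


class EmptyMatrixError(ValueError):
    """A filtering step removed every gene."""


class DegenerateNullError(ValueError):
    """The control distribution has zero spread, so a z-statistic is undefined."""
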