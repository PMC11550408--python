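"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigError(ValidationError):
    """A configuration object is inconsistent or names an unknown option."""


class CapacityError(RuntimeError):
    """A sampler could not satisfy its constraints within its attempt budget."""
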