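"""Exception hierarchy shared across the pipeline."""


class FatsigError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FatsigError, ValueError):
    """A simulation or run configuration violates its invariants."""


class FormatError(FatsigError, ValueError):
    """A file violates the structural contract of its format."""


class ValidationError(FatsigError, ValueError):
    """Parsed data violate a domain invariant (negative time, bad flag...)."""


class SchemaError(FormatError):
    """A serialized artifact has a missing/incompatible schema."""


class DegenerateDataError(FatsigError, ValueError):
    """An operation received data it is undefined on (constant profile,
    single-class labels, empty sample intersection...)."""
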