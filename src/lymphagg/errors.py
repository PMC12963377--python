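"""Exception hierarchy shared across the package."""


class LymphAggError(Exception):
    """Base class for all package errors."""


class FormatError(LymphAggError, ValueError):
    """A file does not conform to the expected external format."""


class ValidationError(LymphAggError, ValueError):
    """In-memory data violates a declared invariant."""


class GenerationError(LymphAggError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""
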