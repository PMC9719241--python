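"""Exception hierarchy for ergwave."""


class ErgwaveError(Exception):
    """Base class for all ergwave errors."""


class ValidationError(ErgwaveError, ValueError):
    """A domain object or argument violates its invariants."""


class SchemaError(ErgwaveError, ValueError):
    """Tabular input does not match the expected schema."""


class FitError(ErgwaveError, RuntimeError):
    """Model fitting could not be performed on the given input."""
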