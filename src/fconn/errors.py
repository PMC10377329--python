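"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A configuration or domain object violates its invariants."""


class DegenerateInputError(ValueError):
    """Input is degenerate for the requested estimator (e.g. constant series)."""


class ParseError(ValueError):
    """A file on disk could not be parsed into a domain object."""
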