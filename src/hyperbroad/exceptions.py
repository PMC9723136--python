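"""Exception hierarchy shared across the package."""


class HyperbroadError(Exception):
    """Base class for all package errors."""


class ParseError(HyperbroadError, ValueError):
    """A delimited-text file could not be parsed (ragged rows, bad cells)."""


class ValidationError(HyperbroadError, ValueError):
    """An input violates a documented contract (shapes, labels, ranges)."""


class FitError(HyperbroadError, RuntimeError):
    """Model training failed (divergence, degenerate data)."""
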