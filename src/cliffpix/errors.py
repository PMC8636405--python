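"""Exception hierarchy shared across the package."""


class CliffpixError(Exception):
    """Base class for all package errors."""


class UsageError(CliffpixError):
    """The caller violated an interface contract (bad argument, bad config)."""


class DataError(CliffpixError):
    """The input data violate an assumption (unparsable structure, empty
    table, single-class labels, ...)."""
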