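"""Exception hierarchy shared across the package."""


class ChromdepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChromdepError):
    """An input file does not conform to its expected format."""


class DataError(ChromdepError):
    """Input data are structurally valid but unusable (empty, degenerate, ...)."""
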