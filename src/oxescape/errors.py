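"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, data 3, numerical 4).
"""


class OxescapeError(Exception):
    """Base class for package errors."""


class ConfigError(OxescapeError):
    """Invalid or incomplete configuration."""


class DataError(OxescapeError):
    """Unreadable, inconsistent or insufficient input data."""


class NumericalError(OxescapeError):
    """A numerical procedure failed (non-convergence, unverifiable window)."""
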