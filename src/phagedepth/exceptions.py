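"""Exception hierarchy.

ConfigError covers invalid parameters, thresholds, and missing inputs
detected before a run starts; DataError covers malformed or degenerate
data discovered while computing. The CLI maps them to exit codes 2 and 3.
"""


class PhageDepthError(Exception):
    """Base class for all package errors."""


class ConfigError(PhageDepthError):
    """Invalid configuration, thresholds, or missing input files."""


class DataError(PhageDepthError):
    """Malformed, inconsistent, or degenerate data."""
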