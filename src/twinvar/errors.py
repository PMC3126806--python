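"""Exception hierarchy.

``ConfigError`` signals a bad configuration (CLI exit code 2), ``DataError``
a violation of the cohort data contract (CLI exit code 3).
"""


class TwinvarError(Exception):
    """Base class for all package errors."""


class ConfigError(TwinvarError):
    """Invalid configuration: missing columns, bad thresholds, bad options."""


class DataError(TwinvarError):
    """Input data violates an invariant (duplicate persons, mixed-zygosity pairs, ...)."""
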