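"""Exception hierarchy shared across the pipeline.

Three families matter downstream: bad user input (tables, volumes, grids),
bad configuration (unknown model kinds, out-of-range item indices), and
statistically degenerate data (zero-variance patterns, all-tied scores).
The CLI maps them to distinct exit codes.
"""


class IsrsaError(Exception):
    """Base class for all package errors."""


class InputError(IsrsaError):
    """Malformed or inconsistent user-supplied data."""


class ConfigError(IsrsaError):
    """Invalid configuration value or combination."""


class DegenerateDataError(IsrsaError):
    """Data that makes a statistic undefined (e.g. zero rank variance)."""
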