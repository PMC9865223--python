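"""Exception hierarchy: data errors vs configuration errors.

The CLI maps :class:`DataError` to exit code 1 and :class:`ConfigError`
to exit code 2.
"""


class VegindexError(Exception):
    """Base class for all toolkit errors."""


class DataError(VegindexError):
    """Invalid or inconsistent input data (grids, samples, labels)."""


class ConfigError(VegindexError):
    """Invalid configuration (band maps, hierarchy specs, stage plans)."""
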