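"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is a bug.
"""


class SexscanError(Exception):
    """Base class for all sexscan errors."""


class ConfigError(SexscanError):
    """The run configuration or sample sheet is invalid."""


class DataError(SexscanError):
    """Input data are malformed or degenerate (e.g. BAM/index mismatch)."""
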