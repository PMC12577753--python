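"""Exception hierarchy shared across the pipeline."""


class IncitePipeError(Exception):
    """Base class for all package errors."""


class FormatError(IncitePipeError, ValueError):
    """An on-disk file violates the expected format (named in the message)."""


class ConfigError(IncitePipeError, ValueError):
    """A configuration, design, or cross-reference is invalid."""


class DegenerateDataError(IncitePipeError, ValueError):
    """Input data admit no meaningful estimate (constant column, empty group)."""
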