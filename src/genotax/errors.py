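"""Exception hierarchy shared across the pipeline stages."""


class GenotaxError(Exception):
    """Base class for all package errors."""


class FormatError(GenotaxError):
    """Malformed input file or record (CLI exit code 2)."""


class StageError(GenotaxError):
    """A pipeline stage failed mid-run (CLI exit code 3)."""
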