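"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class SpeccountError(Exception):
    """Base class for all package errors."""


class MalformedInputError(SpeccountError):
    """An input table, FASTA or annotation file violates its contract."""


class FdrExceededError(SpeccountError):
    """The realized identification FDR exceeds the configured maximum."""
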