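"""Exception hierarchy shared across the package."""


class EcgReconError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EcgReconError, ValueError):
    """A caller-supplied argument violates an operation's contract."""


class InvalidStateError(EcgReconError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. untrained model)."""


class CorruptRecordError(EcgReconError):
    """Stored record fails its checksum."""


class FormatError(EcgReconError):
    """Stored record files are mutually inconsistent or use an unsupported dialect."""


class DegenerateLeadError(EcgReconError):
    """A lead is constant, so min-max normalization is undefined."""


class DegenerateAttentionError(EcgReconError):
    """Every key position is masked for some attention query."""


class UndefinedMetricError(EcgReconError):
    """A metric's denominator (energy, range) is zero."""


class NoDiscordanceError(EcgReconError):
    """McNemar's test is undefined when both discordant counts are zero."""
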