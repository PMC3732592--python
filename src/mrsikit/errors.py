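"""Exception hierarchy shared across the toolkit.

Usage errors (bad arguments, wrong domain) and data errors (corrupt files,
failed integrity checks) are kept distinct so the command line surface can map
them onto different exit codes.
"""


class MrsError(Exception):
    """Base class for all toolkit errors."""


class DomainError(MrsError):
    """An operation was applied to data in the wrong spectral/spatial domain."""


class OutOfRangeError(MrsError, ValueError):
    """A ppm value or index falls outside the axis it was addressed on."""


class FormatError(MrsError):
    """A file is not in (or declares itself inconsistently with) a supported format."""


class CorruptionError(MrsError):
    """A file's payload disagrees with its own declared structure."""


class IntegrityError(CorruptionError):
    """A stored digest does not match the recomputed digest of a payload."""
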