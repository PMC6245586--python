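"""Exception hierarchy for the mitescan pipeline.

Every stage raises a subclass of :class:`MitescanError`, so callers (and
the command-line wrapper) can distinguish user-input problems from bugs.
"""


class MitescanError(Exception):
    """Base class for all mitescan errors."""


class InputError(MitescanError):
    """A required input file is missing or unreadable."""


class FormatError(MitescanError):
    """An input file is readable but malformed (e.g. empty FASTA record)."""


class ConfigError(MitescanError):
    """An invalid parameter combination (e.g. fragment shorter than overlap)."""


class TrainingError(MitescanError):
    """The scoring model cannot be trained from the supplied sequence sets."""


class PlacementError(MitescanError):
    """The synthetic generator cannot place implants without overlap."""
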