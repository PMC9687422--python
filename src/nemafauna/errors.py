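"""Exception hierarchy for the nemafauna package.

Undefined index values are signalled with typed exceptions carrying a
human-readable reason, never silent zeros, NaNs or infinities.  The
table-building layer catches :class:`UndefinedIndexError` and records the
reason next to an ``NA`` marker.
"""


class NemafaunaError(Exception):
    """Base class for all package errors."""


class ValidationError(NemafaunaError):
    """Input violates a documented contract (bad value, malformed row)."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class UnknownTaxonError(NemafaunaError):
    """A genus could not be resolved against the taxonomy reference."""

    def __init__(self, genera):
        self.genera = sorted({str(g) for g in genera})
        super().__init__(
            "unknown taxa not in the taxonomy reference: " + ", ".join(self.genera)
        )


class LinkageError(ValidationError):
    """Counts reference a sample id absent from the metadata (or vice versa)."""


class DesignError(NemafaunaError):
    """The statistical design does not support the requested analysis."""


class ConfigError(ValidationError):
    """A simulation or run configuration is invalid."""


class UndefinedIndexError(NemafaunaError):
    """An ecological index is undefined for this community.

    Parameters
    ----------
    index : str
        Short index name (``"WI"``, ``"J_prime"``, ...).
    reason : str
        Why the value is undefined (e.g. ``"no plant parasites (Pp = 0)"``).
    """

    def __init__(self, index: str, reason: str):
        self.index = index
        self.reason = reason
        super().__init__(f"{index} undefined: {reason}")
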