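"""Exception hierarchy for the repertoire-analysis pipeline.

All package errors derive from :class:`RepertoireError` so callers can
distinguish data/configuration problems from programming errors.
"""


class RepertoireError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RepertoireError):
    """A table or gene name does not conform to the expected layout."""


class EmptyInputError(RepertoireError):
    """An input file or data section contains no usable data."""


class ConfigurationError(RepertoireError):
    """An invalid parameter combination or unknown registry entry."""


class DataInconsistencyError(RepertoireError):
    """Records contradict each other (e.g. mixed frame status per clonotype)."""


class UndefinedSimilarityError(RepertoireError):
    """A similarity index is requested for an empty repertoire.

    Raised instead of silently returning 0 so that samples emptied by
    upstream filters surface as errors rather than as fake "no overlap".
    """


class InsufficientDataError(RepertoireError):
    """Too few observations for the requested statistic."""
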