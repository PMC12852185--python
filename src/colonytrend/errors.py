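"""Exception hierarchy for colonytrend.

All package-specific failures derive from :class:`ColonyTrendError` so that
callers (and the CLI) can distinguish domain errors from programming errors.
"""


class ColonyTrendError(Exception):
    """Base class for all colonytrend errors."""


class SchemaError(ColonyTrendError):
    """A tabular input is missing required columns or has an unusable layout."""


class ValidationError(ColonyTrendError):
    """Input rows violate a data invariant (duplicates, negative counts, ...)."""


class DegenerateInputError(ColonyTrendError):
    """The input is structurally valid but the requested fit is undefined on it."""


class UndefinedRateError(ColonyTrendError):
    """A growth rate cannot be computed (e.g. a zero count under a log model)."""


class AlignmentError(ColonyTrendError):
    """Two colony-indexed inputs do not refer to the same set of colonies."""
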