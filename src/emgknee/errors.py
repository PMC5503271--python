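"""Exception hierarchy for the emgknee package."""


class EmgError(Exception):
    """Base class for all emgknee errors."""


class FormatError(EmgError):
    """A file is missing required columns or has an unusable layout."""


class ParseError(EmgError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(EmgError):
    """A domain object violates one of its invariants."""


class ParameterError(EmgError):
    """A spec/parameter value is outside its admissible range."""


class DomainError(EmgError):
    """An operation was applied to input outside its mathematical domain."""


class DegenerateDataError(EmgError):
    """Data too degenerate for the requested statistic or fit."""


class StratificationError(EmgError):
    """A class has too few members for the requested fold count."""


class ConfigurationError(EmgError):
    """An unknown feature name, feature set, or config key."""


class LabelingError(EmgError):
    """A recording's session label is unknown to the segmenter."""


class OnsetNotFoundError(EmgError):
    """No movement onset detected within the search horizon after a tone."""
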