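"""Exception hierarchy for the pipeline."""


class CrowdVocError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CrowdVocError):
    """A data file does not conform to the expected tab-separated dialect."""


class RowError(FormatError):
    """A single row of a metadata table is malformed.

    Carries the 1-based line number of the offending row (header = line 1).
    """

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class WindowError(CrowdVocError):
    """A requested time window does not overlap the available series."""


class GapError(CrowdVocError):
    """A screening window contains a data gap too long to interpolate."""


class FitError(CrowdVocError):
    """The box-model fit could not be computed."""


class ConfigError(CrowdVocError):
    """A run configuration is inconsistent or incomplete."""
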