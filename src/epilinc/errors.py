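"""Exception hierarchy shared across the pipeline."""


class EpilincError(Exception):
    """Base class for every error raised by this package."""


class ParseError(EpilincError):
    """A malformed record in an input file.

    Carries the offending file and 1-based line number when known.
    """

    def __init__(self, message, path=None, line_number=None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line_number is not None:
            loc += f":{line_number}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line_number = line_number


class ConfigurationError(EpilincError):
    """A parameter or input combination that can never be valid."""


class UndefinedResultError(EpilincError):
    """A statistic or score requested on input where it is undefined
    (e.g. zero total coverage in a group, zero library size)."""


class TrainingError(EpilincError):
    """Model training received degenerate input (empty or single-class)."""


class CoordinateError(EpilincError):
    """A genomic interval falls outside its contig."""
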