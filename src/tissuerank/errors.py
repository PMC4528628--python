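"""Exception types shared across the package."""


class TissueRankError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(TissueRankError):
    """A tabular input file violates its format contract.

    Where possible the message names the offending line number.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DegenerateExperimentError(TissueRankError):
    """An experiment has too few genes for robust statistics (< 3)."""
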