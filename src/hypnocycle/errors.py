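"""Exception types shared across the package."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but has no defined answer.

    Typical cases: a constant hypnodensity series (zero correlation
    denominator) or an embedding whose every dimension has zero variance.
    """


class HypnodensityParseError(ValueError):
    """Raised when a hypnodensity/hypnogram text file cannot be parsed.

    Carries the 1-based line (or row) number of the first offending record
    when it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
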