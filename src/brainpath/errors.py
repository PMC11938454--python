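"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a stated precondition (bad frequency, shape mismatch...)."""


class ExclusionSignal(ValueError):
    """Participant must be excluded (e.g. no parental information)."""


class RankDeficientDesign(ValidationError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")
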