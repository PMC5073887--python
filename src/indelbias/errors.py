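"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Input data is internally inconsistent (e.g. VCF REF disagrees with FASTA)."""


class ParameterError(ValueError):
    """A parameter combination is infeasible."""


class CapacityError(ValueError):
    """A synthetic-data request cannot be satisfied (too many loci for the sequence)."""


class AmbiguityOverflowError(RuntimeError):
    """The number of co-optimal alignments exceeds the enumeration cap.

    Carries the cap so callers can report or raise it.
    """

    def __init__(self, cap: int, context: str = ""):
        self.cap = cap
        msg = f"more than {cap} co-optimal alignments"
        if context:
            msg += f" ({context})"
        super().__init__(msg)
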