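"""Exception types shared across the package."""


class CodonUsageError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(CodonUsageError):
    """Raised when a FASTA file is structurally malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class CdsValidationError(CodonUsageError):
    """Raised when a record failing frame validation is used without force."""


class UndefinedCompositionError(CodonUsageError):
    """Composition requested on input with no countable positions."""


class UndefinedStatisticError(CodonUsageError):
    """Statistic requested on an empty or degenerate codon count table."""


class UndefinedRegressionError(CodonUsageError):
    """Regression on too few points or zero-variance predictor."""


class InsufficientGroupsError(CodonUsageError):
    """Cross-group range statistics need at least two groups."""


class InsufficientOverlapError(CodonUsageError):
    """Too few shared codons between two RSCU tables to correlate."""


class GeneratorSpecError(CodonUsageError):
    """Invalid synthetic-data generator specification."""


class FeasibilityError(CodonUsageError):
    """Requested compositional target unreachable by codon tilting."""
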