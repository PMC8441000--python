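"""Exception hierarchy shared across the pipeline."""


class PrsGxeError(Exception):
    """Base class for all package errors."""


class ParseError(PrsGxeError):
    """A file could not be parsed or failed row-level validation."""


class ValidationError(PrsGxeError):
    """Inputs violate a documented precondition or invariant."""


class AlignmentError(PrsGxeError):
    """Genotypes could not be aligned to GWAS effect alleles."""


class ConstantInputError(PrsGxeError):
    """A statistic is undefined because an input vector is constant."""
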