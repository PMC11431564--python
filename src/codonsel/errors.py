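"""Exception hierarchy shared across the package."""


class CodonselError(Exception):
    """Base class for all package errors."""


class AlignmentError(CodonselError):
    """Malformed alignment: unequal lengths, length not divisible by 3, ..."""


class ContentError(CodonselError):
    """Invalid content, e.g. an in-frame stop codon or an all-missing alignment."""


class LookupFailure(CodonselError):
    """A named entity (taxon, gene, stage) is absent."""


class ReconciliationError(CodonselError):
    """Taxon sets of tree and alignment disagree; message lists the symmetric difference."""


class ValidationFailure(CodonselError):
    """An annotation or configuration value violates its contract."""


class UsageError(CodonselError):
    """An operation was invoked with incompatible arguments."""


class NumericalError(CodonselError):
    """A numerical failure, e.g. a site with zero likelihood."""
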