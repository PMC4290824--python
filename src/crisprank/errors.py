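"""Exception hierarchy shared across the pipeline."""


class CrisprankError(Exception):
    """Base class for all package errors."""


class CountTableFormatError(CrisprankError):
    """Malformed count table (duplicate ids, negative/non-integer counts, ...)."""


class GMTFormatError(CrisprankError):
    """Malformed GMT gene-set line."""


class DesignError(CrisprankError):
    """Invalid control/treatment sample specification."""


class NormalizationError(CrisprankError):
    """Size factors cannot be computed for this table."""


class MomentsError(CrisprankError):
    """Sample moments require at least two replicates."""


class VarianceModelError(CrisprankError):
    """Mean-variance regression has too few usable points."""


class DispersionError(CrisprankError):
    """Negative-binomial parameters require variance strictly above the mean."""
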