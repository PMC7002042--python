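"""Exception hierarchy shared across the package."""


class VasculomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VasculomeError):
    """A configuration is internally inconsistent (e.g. gene-role budgets exceed n_genes)."""


class DomainError(VasculomeError, ValueError):
    """An argument lies outside its mathematical domain (e.g. a fraction outside [0, 1])."""


class DegenerateInputError(VasculomeError, ValueError):
    """Input is formally valid but the requested statistic is undefined on it
    (e.g. a rank correlation of an all-tied vector)."""


class ModelError(VasculomeError):
    """A model cannot be fit as specified (e.g. rank-deficient design matrix)."""


class ParseError(VasculomeError):
    """A file could not be parsed; the message carries the offending line where known."""
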