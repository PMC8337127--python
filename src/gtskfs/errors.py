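"""Exception hierarchy shared across the package."""


class GtskError(Exception):
    """Base class for all package errors."""


class SchemaError(GtskError):
    """A required column is missing or an unexpected column was supplied."""


class ParseError(GtskError):
    """A cell could not be parsed as a number; carries the offending row."""


class DegenerateFeatureError(GtskError):
    """A feature column has zero variance and cannot be standardized."""


class DomainError(GtskError):
    """An input lies outside the mathematical domain of a formula."""


class NoSolutionError(GtskError):
    """A root-finding target is outside the achievable range."""


class InfeasibleError(GtskError):
    """Problem-size constraints violated (e.g. more clusters than samples)."""


class DegenerateRuleError(GtskError):
    """A fuzzy cluster has zero total membership; no premise can be formed."""


class ShapeError(GtskError):
    """Array dimensions are inconsistent with the model."""


class GraphError(GtskError):
    """The similarity graph is degenerate (zero-norm row / isolated node)."""


class RankDeficiencyError(GtskError):
    """The unregularized normal matrix is singular; a ridge term is needed."""


class FormatError(GtskError):
    """A serialized model file is corrupted or has an unknown schema."""
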