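"""Exception hierarchy shared across the package."""


class PersistLsdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PersistLsdError):
    """A file or cell does not conform to the expected format."""


class AlignmentError(PersistLsdError):
    """Covariates cannot be aligned to the detection-history site order."""


class EstimationError(PersistLsdError):
    """A model cannot be estimated from the data as given."""


class IdentifiabilityError(EstimationError):
    """The requested parameters are not separately identifiable."""


class SelectionError(PersistLsdError):
    """Model ranking is impossible (e.g. every candidate was excluded)."""


class DegenerateStatisticError(PersistLsdError):
    """A goodness-of-fit statistic could not be formed (all cells pooled away)."""


class ConfigError(PersistLsdError):
    """A simulation or run configuration is invalid."""
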