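"""Exception hierarchy for actitrial."""


class ActitrialError(Exception):
    """Base class for all actitrial errors."""


class InvalidParameterError(ActitrialError, ValueError):
    """A distributional or design parameter is outside its valid range."""


class DesignError(ActitrialError, ValueError):
    """The trial design is infeasible (e.g. an arm would receive 0 participants)."""


class AnalysisError(ActitrialError, RuntimeError):
    """The primary analysis cannot be run (e.g. no analysable participants)."""


class EstimabilityError(AnalysisError):
    """The treatment effect is not estimable (single-arm input)."""


class SingularityError(AnalysisError):
    """The design matrix of the primary analysis is rank deficient."""


class CellError(ActitrialError, RuntimeError):
    """Too many replications of a simulation cell failed to produce a fit."""


class ConfigError(ActitrialError, ValueError):
    """A run configuration is malformed or contains unknown keys."""
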