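"""Exception hierarchy shared by all pipeline stages."""


class MorphometryError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MorphometryError):
    """A simulation or analysis configuration violates its invariants."""


class InsufficientDataError(MorphometryError):
    """Too few non-missing observations to compute the requested statistic."""


class CollinearityError(MorphometryError):
    """A covariance or cross-product matrix is singular or near-singular."""


class IncompleteRecordError(MorphometryError):
    """A record is missing a measurement required by a model or rule."""


class SchemaError(MorphometryError):
    """An input file does not match the expected CSV schema."""


class EmptyModelError(MorphometryError):
    """Backward-stepwise selection removed every candidate variable."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []
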