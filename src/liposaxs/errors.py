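"""Exception hierarchy for liposaxs."""


class LipoSAXSError(Exception):
    """Base class for all liposaxs errors."""


class InvalidProfileError(LipoSAXSError):
    """Shell profile violates an invariant (ordering, positivity, finiteness)."""


class InvalidConfigurationError(LipoSAXSError):
    """A combination of model parameters is physically inconsistent."""


class UndefinedRgError(LipoSAXSError):
    """Radius of gyration undefined (zero or negative net excess scattering mass)."""


class AliasingError(LipoSAXSError):
    """q grid too sparse for the requested real-space extent."""


class NoGuinierRegimeError(LipoSAXSError):
    """No low-q window with a negative ln I vs q^2 slope."""


class RegridRequiredError(LipoSAXSError):
    """Two curves do not share a common q grid."""


class FitFailureError(LipoSAXSError):
    """Optimizer exhausted its budget without converging."""


class OutOfRangeError(LipoSAXSError):
    """Requested value lies outside a tabulated relation."""


class ResolutionError(LipoSAXSError):
    """Numerical resolution insufficient (e.g. non-monotone tabulated relation)."""


class ConfigError(LipoSAXSError):
    """Malformed or unknown configuration content."""


class CurveParseError(LipoSAXSError):
    """A curve file contains a malformed row."""


class PipelineStageError(LipoSAXSError):
    """A pipeline stage failed; partial outputs were persisted."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
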