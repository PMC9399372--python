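"""Exception types shared across the package."""


class RadiosigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RadiosigError, ValueError):
    """An invalid simulation or pipeline configuration."""


class GenerationError(RadiosigError, RuntimeError):
    """The synthetic generator produced structurally invalid output."""


class InsufficientDataError(RadiosigError, ValueError):
    """Too few samples / shared cell lines for the requested statistic."""


class StageError(RadiosigError, RuntimeError):
    """A pipeline stage produced an empty gene set.

    The message names the stage so a failed run is diagnosable from the log.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
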