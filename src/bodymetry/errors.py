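"""Exception hierarchy shared across the pipeline stages."""


class BodymetryError(Exception):
    """Base class for all package-specific failures."""


class ValidationError(BodymetryError, ValueError):
    """Invalid argument, configuration, or domain-type invariant violation."""


class EmptySilhouetteError(BodymetryError):
    """Segmentation produced no foreground pixels."""


class InsufficientResolutionError(BodymetryError):
    """Requested raster scale is too coarse to represent the body."""


class StageError(BodymetryError):
    """Pipeline failure wrapped with the name of the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
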