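"""Exception hierarchy. Stitching errors carry the pipeline stage that failed."""

from __future__ import annotations


class TcrweaveError(Exception):
    """Base class for all package errors."""


class ReferenceError(TcrweaveError):
    """Malformed or inconsistent germline reference input."""


class UnknownGeneError(ReferenceError):
    pass


class UnknownAlleleError(ReferenceError):
    pass


class CodonTableError(TcrweaveError):
    pass


class StitchError(TcrweaveError):
    """Assembly failure; ``stage`` names the step that failed."""

    def __init__(self, message: str, stage: str = "stitch"):
        super().__init__(message)
        self.stage = stage


class JunctionAnchorError(StitchError):
    """The junction's terminal residue cannot be anchored at the J motif."""

    def __init__(self, message: str):
        super().__init__(message, stage="junction_anchor")


class SeamlessOverlapError(StitchError):
    """Seamless-mode overlap below the minimum exact-match length."""

    def __init__(self, message: str, stage: str = "seamless_overlap"):
        super().__init__(message, stage=stage)


class FrameError(StitchError):
    def __init__(self, message: str):
        super().__init__(message, stage="frame")


class BatchError(TcrweaveError):
    pass


class AnnotationError(TcrweaveError):
    pass


class SimulationError(TcrweaveError):
    pass
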