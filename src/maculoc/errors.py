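"""Exception hierarchy for the detection pipeline.

Stage failures are ordinary, expected outcomes on poor-quality images
(bright lesions, washed-out discs); they carry enough context for the
end-to-end driver to emit a structured, stage-attributed failure report
instead of a stack trace.
"""


class MaculocError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MaculocError):
    """Input image or argument violates a precondition."""


class ConfigError(MaculocError):
    """Configuration file has unknown keys or out-of-range values."""


class ODNotFoundError(MaculocError):
    """Optic-disc segmentation produced no usable blob."""


class TemporalTieError(MaculocError):
    """Left/right vessel-pixel counts are exactly equal; no direction call.

    Carries both counts so the caller can report the tie instead of guessing.
    """

    def __init__(self, left_count: int, right_count: int):
        self.left_count = int(left_count)
        self.right_count = int(right_count)
        super().__init__(
            f"temporal direction tie: left={self.left_count} right={self.right_count}"
        )


class RoiOutOfBoundsError(MaculocError):
    """Macular ROI falls entirely outside the image (upstream failure)."""


class ReportParseError(MaculocError):
    """A serialized detection report is malformed."""


class InvalidSpecError(MaculocError):
    """A synthetic-image spec violates its anatomical invariants."""
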