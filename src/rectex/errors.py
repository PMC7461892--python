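"""Exception hierarchy for the rectex pipeline.

All rectex-specific failures derive from :class:`RectexError` so that the
CLI can distinguish pipeline problems from programming errors.
"""


class RectexError(Exception):
    """Base class for all rectex errors."""


class ShapeMismatchError(RectexError):
    """Image and mask do not share a pixel grid."""


class EmptyMaskError(RectexError):
    """A mask contains no (or too few) foreground pixels."""


class UndefinedFeatureError(RectexError):
    """A texture feature is mathematically undefined on this ROI.

    Carries the feature name so callers can flag it as missing instead of
    aborting a whole case.
    """

    def __init__(self, feature: str, reason: str = ""):
        self.feature = feature
        msg = f"feature {feature!r} is undefined"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


class DegenerateDataError(RectexError):
    """Input data degenerate for the requested statistic (zero variance,
    empty margin, single class, ...)."""


class PipelineStageError(RectexError):
    """A pipeline stage failed; the message names the stage."""
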