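"""Exception hierarchy for the segmentation pipeline."""


class RsaSegError(Exception):
    """Base class for all package-specific errors."""


class InputError(RsaSegError):
    """Invalid or unreadable input (empty directory, mixed series, bad spec)."""


class UnsupportedFormatError(RsaSegError):
    """Input in a format the reader does not handle (e.g. colour DICOM)."""


class CorruptFixtureError(RsaSegError):
    """Raw-volume fixture file whose header and payload disagree."""


class NoPeakError(RsaSegError):
    """Surface histogram has no qualifying peak: no detectable bimodal
    enamel/cementum contrast on the tooth surface."""


class ThresholdFailureError(RsaSegError):
    """A first peak was found but no local minimum follows it, so no
    segmentation threshold can be placed."""


class DegenerateInputWarning(UserWarning):
    """Non-fatal degenerate condition (all-air volume, empty edge map, ...)."""
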