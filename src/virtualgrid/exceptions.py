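"""Exception hierarchy for the virtualgrid package."""


class VirtualGridError(Exception):
    """Base class for all package-specific errors."""


class SizeError(VirtualGridError, ValueError):
    """An image, kernel or ROI does not fit the requested geometry."""


class UnitError(VirtualGridError, ValueError):
    """Physical units (pixel pitch) of two objects disagree."""


class FormatError(VirtualGridError, ValueError):
    """An image file has an unsupported layout or bit depth."""


class EstimationError(VirtualGridError, RuntimeError):
    """A statistical estimate cannot be formed from the available data."""
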