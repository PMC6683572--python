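"""Exception hierarchy shared across coverimg modules."""


class CoverimgError(Exception):
    """Base class for all coverimg errors."""


class ChannelLimitError(CoverimgError):
    """Raised when a selection channel list is already at its maximum size."""


class SelectionFormatError(CoverimgError):
    """Raised when a selection file fails to parse or validate."""


class SelectionVersionError(SelectionFormatError):
    """Raised for selection files with an unknown schema version."""


class SelectionMismatchError(CoverimgError):
    """Raised when paired selections disagree on metric or tolerance."""


class UnsupportedImageError(CoverimgError):
    """Raised for undecodable files or unsupported bit depths."""


class AnisotropicResolutionError(CoverimgError):
    """Raised when horizontal and vertical embedded resolution disagree."""


class RegionBoundsError(CoverimgError):
    """Raised when a rectangle or coordinate falls outside the image."""


class AreaUnavailableError(CoverimgError):
    """Raised when a physical-area computation is requested without DPI."""


class BatchConfigError(CoverimgError):
    """Raised for unusable batch configurations (empty input set etc.)."""
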