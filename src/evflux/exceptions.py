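"""Exception types raised by the evflux pipelines."""


class EvfluxError(Exception):
    """Base class for all evflux-specific failures."""


class MissingPageError(EvfluxError):
    """A channel map references a TIFF page that the file does not contain."""


class DimensionMismatchError(EvfluxError):
    """Channel grids within one field do not share identical dimensions."""


class UnreadableFileError(EvfluxError):
    """A referenced image file is absent or cannot be parsed."""


class PlacementError(EvfluxError):
    """Synthetic object placement failed under the spacing constraints."""


class EmptyMaskWarning(UserWarning):
    """Segmentation produced an all-background mask (legal, but flagged)."""
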