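"""Exception hierarchy for leafchem.

All library errors derive from :class:`LeafchemError` so callers can trap
them in one clause; each subclass also inherits the closest built-in
(``ValueError``/``IOError``) so generic handling keeps working.
"""


class LeafchemError(Exception):
    """Base class for all leafchem errors."""


class ConfigurationError(LeafchemError, ValueError):
    """Invalid configuration value (window sizes, thresholds, panel entries)."""


class FormatError(LeafchemError, IOError):
    """Malformed or unsupported on-disk format (ENVI header/binary mismatch)."""


class EmptySegmentationError(LeafchemError, ValueError):
    """Leaf segmentation produced no pixels; the acquisition is unusable."""


class ZeroVarianceError(LeafchemError, ValueError):
    """A constant target (or band) where variance is required."""


class RankError(LeafchemError, ValueError):
    """Requested more latent components than the data can support."""


class DegenerateOpticsError(LeafchemError, ValueError):
    """Synthetic optics drove reflectance entirely outside [0, 1]."""
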