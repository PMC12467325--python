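"""Exception hierarchy for hsiquant."""


class HsiquantError(Exception):
    """Base class for all hsiquant errors."""


class FormatError(HsiquantError):
    """Malformed or inconsistent on-disk cube metadata."""


class CalibrationError(HsiquantError):
    """Dark/white reference frames cannot calibrate the raw cube."""


class SpectralWindowError(HsiquantError):
    """Requested wavelength window does not overlap the axis."""


class MaskError(HsiquantError):
    """A pixel mask is empty or does not match the cube's spatial shape."""


class ROIError(HsiquantError):
    """A region-of-interest set violates its contract (empty or overlapping classes)."""


class LayoutError(HsiquantError):
    """Synthetic cells cannot be placed under the non-overlap constraint."""


class DegenerateSpectraError(HsiquantError):
    """Spectra carry no variance, so a variance-based model is undefined."""
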