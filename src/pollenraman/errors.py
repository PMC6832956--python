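"""Exception hierarchy for the pollen screening workflow."""


class PollenRamanError(Exception):
    """Base class for all errors raised by this package."""


class InvalidProfileError(PollenRamanError):
    """A spectral class profile violates its invariants (e.g. peak off-axis)."""


class PlacementError(PollenRamanError):
    """Particles could not be placed in a field of view under the separation
    constraint within the retry budget."""


class DegenerateImageError(PollenRamanError):
    """An image has a single-valued histogram and cannot be thresholded."""


class SingularTransformError(PollenRamanError):
    """The linear part of a pixel-to-stage transform is not invertible."""


class FocusFailureError(PollenRamanError):
    """Autofocus Gaussian fit failed to converge or produced a best-focus
    position outside the sampled axial range."""


class DegenerateGeometryError(PollenRamanError):
    """Plane fitting received collinear or otherwise rank-deficient points."""


class CalibrationError(PollenRamanError):
    """Wavenumber or intensity calibration could not be established."""


class DegenerateFitError(PollenRamanError):
    """An EMSC fit is unusable (rank-deficient design matrix or a
    multiplicative coefficient below the configured floor)."""


class NormalizationError(PollenRamanError):
    """Area normalization requested over a region with nonpositive total
    intensity."""


class RegionError(PollenRamanError):
    """A requested spectral region does not overlap the axis."""


class SchemaError(PollenRamanError):
    """A table or manifest is missing a required column."""


class ClassificationError(PollenRamanError):
    """Classification is degenerate (e.g. fewer than two classes) or was
    asked to predict a label never seen in training."""
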