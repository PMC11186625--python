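"""Exception hierarchy and warnings used across the package."""


class PhotoReconError(Exception):
    """Base class for all package errors."""


# --- photo preprocessing ---------------------------------------------------

class MarkerNotFound(PhotoReconError):
    """A fiducial marker could not be located with enough keypoint matches."""


class AmbiguousMatch(PhotoReconError):
    """Two fiducial markers resolved to overlapping image locations."""


class DegenerateGeometry(PhotoReconError):
    """Fiducial points are collinear/coincident; no calibration exists."""


class UnassignedComponent(PhotoReconError):
    """A tissue component is missing from the slice-ordering specification."""


class DuplicateAssignment(PhotoReconError):
    """A tissue component was assigned to more than one slice."""


class NonContiguousOrder(PhotoReconError):
    """Slice ordering does not produce consecutive indices from 0."""


class EmptyMaskWarning(UserWarning):
    """Tissue segmentation produced no foreground components."""


# --- reconstruction --------------------------------------------------------

class OpenMeshError(PhotoReconError):
    """Surface mesh is not watertight and could not be closed."""


class SingularTransform(PhotoReconError):
    """Planar transform has non-positive determinant."""


class EmptySliceMask(PhotoReconError):
    """A slice mask has no foreground; centroid initialization impossible."""


class EmptyReference(PhotoReconError):
    """Reference volume has no foreground."""


# --- simulation ------------------------------------------------------------

class OverlapError(PhotoReconError):
    """Phantom structure does not fit inside the requested grid."""


class CountMismatch(PhotoReconError):
    """Reconstruction and ground truth have different slice counts."""


class MissingLabelParams(PhotoReconError):
    """A label in the volume has no Gaussian parameter range configured."""


# --- evaluation ------------------------------------------------------------

class ShapeMismatch(PhotoReconError):
    """Input rasters do not share a common shape."""


class EmptyGroup(PhotoReconError):
    """A statistical group contains no observations."""


class ZeroVariance(PhotoReconError):
    """Correlation undefined: an input vector is constant."""


class RankDeficientDesign(PhotoReconError):
    """GLM design matrix is rank deficient."""


class InvalidCorrelation(PhotoReconError):
    """Correlation coefficients outside (-1, 1) or sample too small."""
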