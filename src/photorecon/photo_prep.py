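"""Calibration, rectification, segmentation and ordering of dissection photographs.

A raw photograph of coronal brain slices is turned into analysis-ready data in
four steps:

1. fiducial markers of known physical geometry are located (SIFT keypoint
   matching against small marker templates);
2. a planar calibration is fitted from the detected points — a full projective
   homography for four rectangle corners, an affine map for two ruler arms, or
   a bare pixel-size for a single known distance;
3. the photograph is resampled onto a regular millimetric grid (perspective
   corrected, grayscale);
4. the tissue is segmented from the background by thresholding + morphology,
   and connected components are grouped into anatomical slices following a
   declarative ordering specification.

Coordinates are (row, col) with the origin at the top-left pixel center;
physical coordinates are in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import label as cc_label, ransac
from skimage.morphology import closing, disk, opening, remove_small_objects
from skimage.transform import SimilarityTransform, warp
from skimage.filters import threshold_otsu

from . import errors

#: luminance weights for color -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Convert an image to float grayscale in [0, 1].

    Integer inputs are divided by their dtype maximum; float inputs are
    assumed to already be on a [0, 1]-ish scale and passed through.
    """
    arr = np.asarray(pixels)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr @ _LUMA
    return arr


@dataclass
class RawPhoto:
    """An unprocessed dissection photograph."""

    pixels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim not in (2, 3) or (p.ndim == 3 and p.shape[2] not in (1, 3)):
            raise ValueError("photo must be 2D or 3-channel")
        if p.shape[0] < 2 or p.shape[1] < 2:
            raise ValueError("photo must be at least 2x2")
        self.pixels = p


@dataclass
class MarkerTemplate:
    """Small template image of one fiducial marker.

    ``center`` is the (row, col) of the marker's reference point inside the
    template; defaults to the template center.
    """

    image: np.ndarray
    name: str = ""
    center: tuple[float, float] | None = None

    def __post_init__(self):
        if self.center is None:
            h, w = np.asarray(self.image).shape[:2]
            self.center = ((h - 1) / 2.0, (w - 1) / 2.0)


# physical geometry attached to a set of fiducial points
@dataclass
class RectangleGeometry:
    width_mm: float   # along columns
    height_mm: float  # along rows

    def __post_init__(self):
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("rectangle dimensions must be positive")


@dataclass
class RulerArmsGeometry:
    """Two ruler arms of known length meeting at a corner point.

    Points are ordered (end of arm 1, end of arm 2, corner).
    """

    length1_mm: float
    length2_mm: float

    def __post_init__(self):
        if self.length1_mm <= 0 or self.length2_mm <= 0:
            raise ValueError("arm lengths must be positive")


@dataclass
class KnownDistanceGeometry:
    distance_mm: float

    def __post_init__(self):
        if self.distance_mm <= 0:
            raise ValueError("distance must be positive")


@dataclass
class FiducialSet:
    """2-4 detected (or clicked) landmark coordinates plus physical geometry."""

    points: np.ndarray  # (k, 2) in (row, col) pixels, sub-pixel
    template: RectangleGeometry | RulerArmsGeometry | KnownDistanceGeometry
    confidences: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or not 2 <= len(pts) <= 4:
            raise ValueError("need 2-4 (row, col) points")
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        if np.any(d[np.triu_indices(len(pts), 1)] == 0):
            raise ValueError("points must be pairwise distinct")
        expected = {RectangleGeometry: 4, RulerArmsGeometry: 3,
                    KnownDistanceGeometry: 2}[type(self.template)]
        if len(pts) != expected:
            raise ValueError(f"{type(self.template).__name__} needs "
                             f"{expected} points, got {len(pts)}")
        self.points = pts


@dataclass
class PlanarCalibration:
    """3x3 homogeneous map from raw pixel (row, col) to physical mm (y, x)."""

    transform: np.ndarray
    pixel_size: float
    mode: Literal["full_perspective", "affine", "scale_only"]

    def __post_init__(self):
        T = np.asarray(self.transform, dtype=float)
        if T.shape != (3, 3) or abs(np.linalg.det(T)) < 1e-15:
            raise ValueError("transform must be an invertible 3x3 matrix")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.transform = T

    def to_mm(self, points_px: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_px)
        h = np.c_[p, np.ones(len(p))] @ self.transform.T
        return h[:, :2] / h[:, 2:]

    def to_px(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_mm)
        h = np.c_[p, np.ones(len(p))] @ np.linalg.inv(self.transform).T
        return h[:, :2] / h[:, 2:]


@dataclass
class CalibratedPhoto:
    """Perspective-corrected grayscale photograph on an isotropic mm grid."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.pixels = np.asarray(self.pixels, dtype=float)


@dataclass
class TissueMask:
    """Binary tissue/background mask with labeled connected components."""

    mask: np.ndarray
    components: np.ndarray  # int labels, contiguous from 1
    pixel_size: float

    @property
    def component_ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.components) if i > 0]


@dataclass
class SliceRecord:
    """One anatomical slice: a set of component ids at an anterior->posterior index."""

    slice_index: int
    component_ids: frozenset[int]


# ---------------------------------------------------------------------------
# fiducial detection
# ---------------------------------------------------------------------------

def _sift_features(img: np.ndarray):
    det = SIFT()
    try:
        det.detect_and_extract(img)
    except RuntimeError:  # no keypoints at all
        return np.zeros((0, 2)), np.zeros((0, 128), dtype=np.uint8)
    return det.keypoints.astype(float), det.descriptors


def detect_fiducials(photo: RawPhoto,
                     markers: Sequence[MarkerTemplate],
                     geometry,
                     min_matches: int = 4,
                     lowe_ratio: float = 0.75,
                     min_separation_px: float | None = None) -> FiducialSet:
    """Locate each fiducial marker in the photograph by SIFT matching.

    Keypoints of each marker template are matched against the photograph's
    keypoints (Lowe ratio test + cross-check); a similarity transform fitted
    by RANSAC maps the template's reference point into the photograph.

    Raises :class:`~photorecon.errors.MarkerNotFound` when a marker has fewer
    than ``min_matches`` matched keypoints, and
    :class:`~photorecon.errors.AmbiguousMatch` when two markers resolve to
    overlapping locations.
    """
    img = to_grayscale(photo.pixels)
    kp_img, desc_img = _sift_features(img)
    if len(kp_img) == 0:
        raise errors.MarkerNotFound("no keypoints detected in photograph")

    centers = []
    confidences = []
    for m in markers:
        tmpl = to_grayscale(m.image)
        kp_t, desc_t = _sift_features(tmpl)
        if len(kp_t) < min_matches:
            raise errors.MarkerNotFound(
                f"marker {m.name!r}: only {len(kp_t)} template keypoints")
        matches = match_descriptors(desc_t, desc_img, cross_check=True,
                                    max_ratio=lowe_ratio)
        if len(matches) < min_matches:
            raise errors.MarkerNotFound(
                f"marker {m.name!r}: {len(matches)} matches < {min_matches}")
        src = kp_t[matches[:, 0]]
        dst = kp_img[matches[:, 1]]
        if len(matches) >= 3:
            model, inliers = ransac((src, dst), SimilarityTransform,
                                    min_samples=2, residual_threshold=3.0,
                                    max_trials=500, rng=0)
            if model is None or inliers is None or inliers.sum() < min_matches:
                raise errors.MarkerNotFound(
                    f"marker {m.name!r}: no consistent similarity model")
            n_in = int(inliers.sum())
        else:
            model = SimilarityTransform()
            model.estimate(src, dst)
            n_in = len(matches)
        # keypoints are (row, col); the similarity was estimated in that
        # same convention, so apply it in (row, col) as well
        cy, cx = m.center
        px = model(np.array([[cy, cx]]))[0]
        centers.append((px[0], px[1]))
        confidences.append(n_in / max(len(matches), 1))

    centers = np.asarray(centers)
    if min_separation_px is None:
        diag = np.mean([np.hypot(*np.asarray(m.image).shape[:2]) for m in markers])
        min_separation_px = diag / 2.0
    d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
    iu = np.triu_indices(len(centers), 1)
    if np.any(d[iu] < min_separation_px):
        raise errors.AmbiguousMatch("two markers resolved to overlapping locations")

    return FiducialSet(points=centers, template=geometry,
                       confidences=np.asarray(confidences))


# ---------------------------------------------------------------------------
# calibration fitting
# ---------------------------------------------------------------------------

def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    p = np.asarray(pts, dtype=float)
    scale = max(np.ptp(p), 1.0)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            for k in range(j + 1, len(p)):
                a = p[j] - p[i]
                b = p[k] - p[i]
                if abs(a[0] * b[1] - a[1] * b[0]) < tol * scale ** 2:
                    return True
    return False


def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Exact 4-point homography src -> dst via direct linear transform."""
    A = []
    for (r, c), (y, x) in zip(src, dst):
        A.append([r, c, 1, 0, 0, 0, -y * r, -y * c, -y])
        A.append([0, 0, 0, r, c, 1, -x * r, -x * c, -x])
    _, _, vt = np.linalg.svd(np.asarray(A, dtype=float))
    H = vt[-1].reshape(3, 3)
    return H / H[2, 2]


def fit_calibration(fiducials: FiducialSet) -> PlanarCalibration:
    """Fit the raw-pixel -> physical-mm planar calibration.

    The mode is forced by the point count: 4 rectangle corners give a full
    perspective homography, 3 ruler-arm points an affine map, 2 points a
    bare isotropic scaling.
    """
    pts = fiducials.points
    geom = fiducials.template

    if isinstance(geom, RectangleGeometry):
        if _collinear(pts):
            raise errors.DegenerateGeometry("3 of the 4 corners are collinear")
        # corner order: top-left, top-right, bottom-right, bottom-left
        h, w = geom.height_mm, geom.width_mm
        dst = np.array([[0.0, 0.0], [0.0, w], [h, w], [h, 0.0]])
        H = _dlt_homography(pts, dst)
        d1 = pts[2] - pts[0]
        d2 = pts[3] - pts[1]
        area_px = 0.5 * abs(d1[0] * d2[1] - d1[1] * d2[0])
        pixel_size = float(np.sqrt((h * w) / area_px))
        return PlanarCalibration(H, pixel_size, "full_perspective")

    if isinstance(geom, RulerArmsGeometry):
        if _collinear(pts):
            raise errors.DegenerateGeometry("ruler arm points are collinear")
        # points: (end of arm 1, end of arm 2, corner)
        dst = np.array([[0.0, geom.length1_mm], [geom.length2_mm, 0.0],
                        [0.0, 0.0]])
        A = np.c_[pts, np.ones(3)]
        coef = np.linalg.solve(A, dst)  # (3, 2): rows of the affine map
        H = np.eye(3)
        H[0, :] = coef[:, 0]
        H[1, :] = coef[:, 1]
        L = H[:2, :2]
        pixel_size = float(np.sqrt(abs(np.linalg.det(L))))
        return PlanarCalibration(H, pixel_size, "affine")

    # two points with a known distance
    d_px = float(np.linalg.norm(pts[1] - pts[0]))
    if d_px == 0:
        raise errors.DegenerateGeometry("the two points coincide")
    ps = geom.distance_mm / d_px
    H = np.diag([ps, ps, 1.0])
    return PlanarCalibration(H, float(ps), "scale_only")


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def rectify(photo: RawPhoto, calib: PlanarCalibration,
            target_pixel_size: float | None = None,
            order: int = 1,
            origin_mm: tuple[float, float] | None = None) -> CalibratedPhoto:
    """Resample the photograph onto a regular grid of ``target_pixel_size`` mm.

    Color inputs are converted to grayscale (luminance weights) before
    resampling; content outside the source footprint is filled with zero.
    ``origin_mm`` pins the physical coordinate of output pixel (0, 0); by
    default the grid covers the whole source footprint.
    """
    if target_pixel_size is None:
        target_pixel_size = calib.pixel_size
    if target_pixel_size <= 0:
        raise ValueError("target_pixel_size must be positive")

    img = to_grayscale(photo.pixels)
    H_img, W_img = img.shape
    corners_px = np.array([[0, 0], [0, W_img - 1],
                           [H_img - 1, W_img - 1], [H_img - 1, 0]], dtype=float)
    corners_mm = calib.to_mm(corners_px)
    ymin, xmin = corners_mm.min(axis=0)
    ymax, xmax = corners_mm.max(axis=0)
    if origin_mm is not None:
        ymin, xmin = origin_mm
    tps = target_pixel_size
    out_h = int(np.floor((ymax - ymin) / tps)) + 1
    out_w = int(np.floor((xmax - xmin) / tps)) + 1

    inv = np.linalg.inv(calib.transform)

    def inverse_map(coords):
        # skimage passes (col, row); work in (row, col) and swap back
        mm = np.c_[coords[:, 1] * tps + ymin, coords[:, 0] * tps + xmin,
                   np.ones(len(coords))]
        src = mm @ inv.T
        src = src[:, :2] / src[:, 2:]
        return src[:, ::-1]

    out = warp(img, inverse_map, output_shape=(out_h, out_w), order=order,
               mode="constant", cval=0.0, preserve_range=True)
    return CalibratedPhoto(pixels=out, pixel_size=float(tps))


# ---------------------------------------------------------------------------
# tissue segmentation
# ---------------------------------------------------------------------------

def segment_tissue(photo: CalibratedPhoto,
                   threshold: float | None = None,
                   min_area_mm2: float = 20.0,
                   morph_radius_mm: float = 1.0) -> TissueMask:
    """Segment brain tissue from the (dark) background.

    ``photo > threshold`` is cleaned with a morphological open-then-close
    (disk of ``morph_radius_mm``), components smaller than ``min_area_mm2``
    are dropped, and survivors labeled with 8-connectivity.  ``threshold``
    defaults to Otsu's value.  Emits :class:`EmptyMaskWarning` when nothing
    survives.
    """
    img = photo.pixels
    if threshold is None:
        threshold = float(threshold_otsu(img))
    binary = img > threshold
    radius_px = int(round(morph_radius_mm / photo.pixel_size))
    if radius_px >= 1:
        selem = disk(radius_px)
        binary = closing(opening(binary, selem), selem)
    min_px = int(np.ceil(min_area_mm2 / photo.pixel_size ** 2))
    if min_px > 1:
        # drop components with area < min_px (max_size is inclusive)
        binary = remove_small_objects(binary, max_size=min_px - 1)
    comps = cc_label(binary, connectivity=2)
    if comps.max() == 0:
        warnings.warn("no tissue component survived segmentation",
                      errors.EmptyMaskWarning)
    return TissueMask(mask=binary.astype(np.uint8), components=comps,
                      pixel_size=photo.pixel_size)


# ---------------------------------------------------------------------------
# slice grouping
# ---------------------------------------------------------------------------

@dataclass
class SliceOrdering:
    """Declarative ordering spec for one photograph.

    ``slices`` lists, in the photograph's native order, the component ids of
    each anatomical slice (several ids when a slice breaks into pieces, e.g.
    around the temporal pole).  ``order`` says whether that native order runs
    anterior-first or posterior-first.
    """

    order: Literal["anterior_first", "posterior_first"]
    slices: list[list[int]]


def group_components(mask: TissueMask, ordering: SliceOrdering) -> list[SliceRecord]:
    """Group connected components into anterior->posterior slice records."""
    available = set(mask.component_ids)
    seen: set[int] = set()
    groups: list[frozenset[int]] = []
    for grp in ordering.slices:
        if not grp:
            raise errors.NonContiguousOrder("empty slice group in ordering spec")
        ids = frozenset(int(i) for i in grp)
        for i in ids:
            if i in seen:
                raise errors.DuplicateAssignment(f"component {i} assigned twice")
            if i not in available:
                raise errors.UnassignedComponent(
                    f"component {i} does not exist in the mask")
            seen.add(i)
        groups.append(ids)
    missing = available - seen
    if missing:
        raise errors.UnassignedComponent(
            f"components {sorted(missing)} not assigned to any slice")
    if ordering.order == "posterior_first":
        groups = groups[::-1]
    return [SliceRecord(slice_index=i, component_ids=g)
            for i, g in enumerate(groups)]
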