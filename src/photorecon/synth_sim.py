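"""Synthetic phantoms, digital slicing, and label-conditioned image synthesis.

Three jobs live here:

* :func:`make_phantom` builds a multi-label 3D "hemisphere" phantom (white
  matter, cortex shell, ventricle, deep gray blobs) and a piecewise-smooth
  intensity rendering — a stand-in for real isotropic MRI volumes so the
  reconstruction can be exercised with known ground truth and no data
  download;
* :func:`digitally_slice` cuts a volume into a photo-like stack every S
  voxels, with optional thickness jitter (slice n drawn from the index
  interval [n-j, n+j] in slice units), an independent random planar affine
  and a smooth multiplicative illumination field per slice, recording every
  ground-truth pose; :func:`reconstruction_error` then scores a
  reconstruction against that truth as the mean foreground voxel
  displacement in mm;
* the generative process for segmentation training data:
  :func:`deform_labels` (smooth 3D deformation + per-coronal-slab jitter),
  :func:`gmm_render` (per-label Gaussians with randomized means/variances),
  and :func:`simulate_training_pair` (digital slicing to a random thickness,
  bias field and brightness/contrast/gamma augmentation, resampling back to
  an isotropic grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from . import errors
from ._interp import bilinear
from .recon_core import (ReconstructionParams, ReconstructionResult,
                         SliceStack, _planar_matrix)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """One phantom structure: an ellipsoid or box in world mm (z, y, x)."""

    kind: Literal["ellipsoid", "box"]
    center: tuple[float, float, float]   # mm, relative to volume center
    radii: tuple[float, float, float]    # semi-axes / half-sizes, mm
    label: int


def _default_structures() -> list[Structure]:
    return [
        Structure("ellipsoid", (0.0, 0.0, 0.0), (19.0, 17.0, 13.5), 1),   # cortex
        Structure("ellipsoid", (0.0, 0.0, 0.0), (15.5, 13.5, 10.5), 2),   # white matter
        # ventricle sits medially, deep gray laterally: disjoint by design so
        # each label keeps its full analytic volume
        Structure("ellipsoid", (1.0, -1.0, -0.5), (7.0, 3.5, 2.5), 3),    # ventricle
        Structure("ellipsoid", (-4.0, 2.0, -6.0), (3.0, 3.0, 2.5), 4),    # thalamus-like
        Structure("ellipsoid", (0.5, 5.0, -5.0), (3.0, 2.5, 2.0), 5),     # caudate-like
        Structure("ellipsoid", (4.0, 0.5, -6.5), (2.5, 2.5, 2.0), 6),     # putamen-like
        Structure("ellipsoid", (-1.0, -5.0, -5.5), (2.5, 2.5, 2.0), 7),   # pallidum-like
    ]


_DEFAULT_BASE_INTENSITY = {0: 0.0, 1: 0.45, 2: 0.85, 3: 0.15,
                           4: 0.55, 5: 0.62, 6: 0.50, 7: 0.68}


@dataclass
class PhantomSpec:
    """Geometry + randomness of a synthetic hemisphere phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 0.7
    structures: list[Structure] = field(default_factory=_default_structures)
    base_intensity: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_INTENSITY))
    hemisphere_cut_mm: float | None = 2.0  # drop tissue with x > this value
    noise_amplitude: float = 0.04
    noise_smoothness_vox: float = 2.0
    seed: int = 0

    def __post_init__(self):
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels) or min(labels, default=1) <= 0:
            raise ValueError("structure labels must be unique positive integers")


@dataclass
class Phantom:
    labels: np.ndarray
    intensity: np.ndarray
    voxel_size: float

    @property
    def mask(self) -> np.ndarray:
        return (self.labels > 0).astype(float)

    @property
    def affine(self) -> np.ndarray:
        """Centered voxel -> mm affine (diagonal, NIfTI-ready)."""
        A = np.diag([self.voxel_size] * 3 + [1.0])
        A[:3, 3] = -(np.array(self.labels.shape) - 1) / 2.0 * self.voxel_size
        return A


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the multi-label phantom and its intensity rendering.

    Deterministic given ``spec.seed``.  Structures are painted in list order
    (later structures overwrite earlier ones); intensities are per-label base
    values plus smooth noise on the foreground.  Raises
    :class:`~photorecon.errors.OverlapError` when a structure does not fit
    inside the grid.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    v = spec.voxel_size
    half = (np.array(shape) - 1) / 2.0 * v
    coords = np.meshgrid(*[(np.arange(s) - (s - 1) / 2.0) * v for s in shape],
                         indexing="ij")
    labels = np.zeros(shape, dtype=np.int32)
    for st in spec.structures:
        c = np.asarray(st.center)
        r = np.asarray(st.radii)
        if np.any(np.abs(c) + r > half + 1e-9):
            raise errors.OverlapError(
                f"structure label {st.label} exceeds the grid")
        if st.kind == "ellipsoid":
            q = sum(((coords[i] - c[i]) / r[i]) ** 2 for i in range(3))
            inside = q <= 1.0
        else:
            inside = np.all([np.abs(coords[i] - c[i]) <= r[i]
                             for i in range(3)], axis=0)
        labels[inside] = st.label
    if spec.hemisphere_cut_mm is not None:
        labels[coords[2] > spec.hemisphere_cut_mm] = 0

    intensity = np.zeros(shape, dtype=float)
    for lab, base in spec.base_intensity.items():
        intensity[labels == lab] = base
    if spec.noise_amplitude > 0:
        noise = gaussian_filter(rng.normal(0.0, 1.0, shape),
                                spec.noise_smoothness_vox)
        peak = np.abs(noise).max()
        if peak > 0:
            noise *= spec.noise_amplitude / peak
        intensity = np.where(labels > 0,
                             np.clip(intensity + noise, 0.0, 1.0), 0.0)
    return Phantom(labels=labels, intensity=intensity, voxel_size=v)


# ---------------------------------------------------------------------------
# digital slicing
# ---------------------------------------------------------------------------

@dataclass
class SlicingConfig:
    """How a volume is cut into a distorted photo stack.

    ``spacing``: one slice every S voxels; ``jitter`` in slice units (the nth
    slice is extracted from the index interval [n-j, n+j]).  Per-slice affine
    distortion ranges and the illumination-field amplitude default to the
    values used throughout the package's simulated experiments; set them to
    zero for undistorted slicing.
    """

    spacing: int = 4
    jitter: float = 0.0
    translation_mm: float = 5.0
    rotation_deg: float = 10.0
    log_scale: float = 0.1
    shear: float = 0.1
    illumination_amplitude: float = 0.15   # max |log field|
    illumination_smoothness_mm: float = 10.0
    nominal_thickness: float | None = None  # defaults to spacing * voxel_size
    drop_empty: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.spacing < 1:
            raise ValueError("spacing must be >= 1")
        if self.jitter < 0 or self.illumination_amplitude < 0:
            raise ValueError("jitter and illumination amplitude must be >= 0")

    @classmethod
    def undistorted(cls, spacing: int, **kw) -> "SlicingConfig":
        return cls(spacing=spacing, translation_mm=0.0, rotation_deg=0.0,
                   log_scale=0.0, shear=0.0, illumination_amplitude=0.0, **kw)


@dataclass
class StackTruth:
    """Ground-truth pose of every simulated slice.

    ``transforms[n]`` maps the slice frame (top-left mm) into the source
    volume's centered in-plane (y, x) mm coordinates; ``z_mm[n]`` is the true
    anterior-posterior position (centered mm).
    """

    transforms: np.ndarray   # (N, 3, 3)
    z_mm: np.ndarray         # (N,)
    indices: np.ndarray      # (N,) extraction indices into the source
    voxel_size: float


@dataclass
class SimulatedStack:
    stack: SliceStack
    truth: StackTruth

    def __post_init__(self):
        if self.truth.transforms.shape[0] != self.stack.n_slices:
            raise ValueError("one ground-truth transform per slice required")


def smooth_log_field(shape, amplitude: float, smoothness_px: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth random field with max |value| == amplitude (log of a
    multiplicative illumination/bias field)."""
    if amplitude <= 0:
        return np.zeros(shape)
    g = gaussian_filter(rng.normal(0.0, 1.0, shape), smoothness_px)
    peak = np.abs(g).max()
    if peak > 0:
        g *= amplitude / peak
    return g


def digitally_slice(intensity: np.ndarray, mask: np.ndarray,
                    voxel_size: float, cfg: SlicingConfig,
                    rng: np.random.Generator | None = None) -> SimulatedStack:
    """Cut a volume into a simulated photo stack with known ground truth.

    Slice n is extracted at anterior-posterior voxel index drawn uniformly
    (integers) from [nS - jS, nS + jS]; each slice then receives a random
    planar affine and a multiplicative smooth illumination field.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    intensity = np.asarray(intensity, dtype=float)
    mask = np.asarray(mask, dtype=float)
    Z, H, W = intensity.shape
    S = cfg.spacing
    if Z < 2 * S:
        raise ValueError("volume anterior-posterior extent must be >= 2*S")
    v = voxel_size
    n_slices = (Z - 1) // S + 1
    off = int(round(cfg.jitter * S))

    u_y = np.arange(H)[:, None] * v * np.ones((1, W))   # slice frame mm
    u_x = np.arange(W)[None, :] * v * np.ones((H, 1))
    ctr = np.array([(H - 1) / 2.0 * v, (W - 1) / 2.0 * v])
    C = np.eye(3)
    C[:2, 2] = -ctr  # slice frame (top-left) -> centered in-plane mm

    out_i, out_m, out_G, zs, idxs = [], [], [], [], []
    for n in range(n_slices):
        idx = n * S
        if off > 0:
            idx = int(np.clip(idx + rng.integers(-off, off + 1), 0, Z - 1))
        # random pose applied about the plane center; with zero amplitudes
        # Gc reduces to the pure centering map and the slice equals the plane
        t = rng.uniform(-cfg.translation_mm, cfg.translation_mm, 2)
        rot = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
        a, b = rng.uniform(-cfg.log_scale, cfg.log_scale, 2)
        h = rng.uniform(-cfg.shear, cfg.shear)
        G = _planar_matrix([t[0], t[1], rot, a, b, h])
        Gc = G @ C  # push-forward truth: slice frame mm -> centered source mm
        # photographed slice: sample the source plane through Gc
        fy = (Gc[0, 0] * u_y + Gc[0, 1] * u_x + Gc[0, 2]) / v + (H - 1) / 2.0
        fx = (Gc[1, 0] * u_y + Gc[1, 1] * u_x + Gc[1, 2]) / v + (W - 1) / 2.0
        si = bilinear(intensity[idx], fy, fx)
        sm = np.clip(bilinear(mask[idx], fy, fx), 0.0, 1.0)
        if cfg.illumination_amplitude > 0:
            sig = cfg.illumination_smoothness_mm / v
            gfield = smooth_log_field((H, W), cfg.illumination_amplitude,
                                      sig, rng)
            si = si * np.exp(gfield)
        out_i.append(si)
        out_m.append(sm)
        out_G.append(Gc)
        zs.append((idx - (Z - 1) / 2.0) * v)
        idxs.append(idx)

    keep = list(range(n_slices))
    if cfg.drop_empty:
        keep = [n for n in keep if out_m[n].sum() > 1e-6]
    if len(keep) < 2:
        raise ValueError("fewer than 2 nonempty slices")

    thickness = cfg.nominal_thickness or S * v
    stack = SliceStack(images=np.stack([out_i[n] for n in keep]),
                       masks=np.stack([out_m[n] for n in keep]),
                       pixel_size=v, nominal_thickness=thickness)
    truth = StackTruth(transforms=np.stack([out_G[n] for n in keep]),
                       z_mm=np.array([zs[n] for n in keep]),
                       indices=np.array([idxs[n] for n in keep]),
                       voxel_size=v)
    return SimulatedStack(stack=stack, truth=truth)


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rigid (R, t) minimizing ||P - (R Q + t)||^2 (rows are points)."""
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    return R, t


def reconstruction_error(result: ReconstructionResult | ReconstructionParams,
                         sim: SimulatedStack, align: bool = True) -> float:
    """Mean displacement (mm) of foreground voxels vs the ground truth poses.

    Every foreground pixel of every slice is mapped once through the
    recovered pose and once through the true pose; the mean Euclidean
    distance is reported after an optimal global rigid alignment of the two
    point sets (the irrelevant common pose), unless ``align=False``.
    """
    params = result.params if isinstance(result, ReconstructionResult) else result
    stack = sim.stack
    if params.phi.shape[0] != stack.n_slices:
        raise errors.CountMismatch(
            f"{params.phi.shape[0]} transforms vs {stack.n_slices} slices")
    zrec = stack.z_positions(params.s)
    p = stack.pixel_size
    P_true, P_rec = [], []
    for n in range(stack.n_slices):
        rr, cc = np.nonzero(stack.masks[n] >= 0.5)
        if len(rr) == 0:
            continue
        u = np.c_[rr * p, cc * p, np.ones(len(rr))]
        G = sim.truth.transforms[n]
        tp = u @ G.T
        Phi = params.phi_matrix(n)
        rp = u @ Phi.T
        P_true.append(np.c_[np.full(len(rr), sim.truth.z_mm[n]),
                            tp[:, 0], tp[:, 1]])
        P_rec.append(np.c_[np.full(len(rr), zrec[n]), rp[:, 0], rp[:, 1]])
    P_true = np.concatenate(P_true)
    P_rec = np.concatenate(P_rec)
    if align:
        R, t = _kabsch(P_true, P_rec)
        P_rec = P_rec @ R.T + t
    return float(np.mean(np.linalg.norm(P_true - P_rec, axis=1)))


# ---------------------------------------------------------------------------
# generative process for segmentation training data
# ---------------------------------------------------------------------------

@dataclass
class GenConfig:
    """Randomization ranges of the label-conditioned generative process."""

    label_params: dict[int, tuple[tuple[float, float], tuple[float, float]]] \
        = field(default_factory=dict)  # label -> ((mean lo, hi), (var lo, hi))
    deformation_amplitude_mm: float = 3.0
    deformation_smoothness_mm: float = 10.0
    slab_jitter_mm: float = 0.5
    slab_jitter_deg: float = 1.0
    thickness_range_mm: tuple[float, float] = (2.0, 8.0)
    thickness_variation_mm: float = 0.3
    bias_amplitude: float = 0.3
    bias_smoothness_mm: float = 15.0
    brightness_range: tuple[float, float] = (-0.15, 0.15)
    contrast_range: tuple[float, float] = (0.7, 1.3)
    gamma_range: tuple[float, float] = (0.6, 1.6)
    output_resolution_mm: float = 1.0
    clip_max: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for lab, (mr, vr) in self.label_params.items():
            if mr[0] > mr[1] or vr[0] > vr[1] or vr[0] < 0:
                raise ValueError(f"ill-ordered ranges for label {lab}")
        for r in (self.thickness_range_mm, self.brightness_range,
                  self.contrast_range, self.gamma_range):
            if r[0] > r[1]:
                raise ValueError("ranges must be well ordered")
        if self.output_resolution_mm <= 0:
            raise ValueError("output resolution must be positive")


def sample_deformation_field(shape, voxel_size: float, amplitude_mm: float,
                             smoothness_mm: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Smooth random displacement field (3, Z, Y, X) in mm.

    The field's maximum displacement norm equals ``amplitude_mm`` (zero
    amplitude gives a zero field), so the configured amplitude is a hard
    bound.
    """
    if amplitude_mm <= 0:
        return np.zeros((3,) + tuple(shape))
    sig = max(smoothness_mm / voxel_size, 1.0)
    f = np.stack([gaussian_filter(rng.normal(0.0, 1.0, shape), sig)
                  for _ in range(3)])
    norms = np.sqrt(np.sum(f * f, axis=0))
    peak = norms.max()
    if peak > 0:
        f *= amplitude_mm / peak
    return f


def deform_labels(labels: np.ndarray, voxel_size: float, cfg: GenConfig,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth random deformation + per-coronal-slab planar jitter.

    Labels are resampled with nearest neighbors, so the output label set is a
    subset of the input's.  Zero amplitudes return the input bitwise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = np.asarray(labels)
    if (cfg.deformation_amplitude_mm <= 0 and cfg.slab_jitter_mm <= 0
            and cfg.slab_jitter_deg <= 0):
        return labels.copy()
    Z, Y, X = labels.shape
    disp = sample_deformation_field(labels.shape, voxel_size,
                                    cfg.deformation_amplitude_mm,
                                    cfg.deformation_smoothness_mm, rng)
    zz, yy, xx = np.meshgrid(np.arange(Z), np.arange(Y), np.arange(X),
                             indexing="ij")
    cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
    src_z = zz + disp[0] / voxel_size
    src_y = yy + disp[1] / voxel_size
    src_x = xx + disp[2] / voxel_size
    if cfg.slab_jitter_mm > 0 or cfg.slab_jitter_deg > 0:
        for k in range(Z):
            dty, dtx = rng.uniform(-cfg.slab_jitter_mm, cfg.slab_jitter_mm, 2)
            th = np.deg2rad(rng.uniform(-cfg.slab_jitter_deg,
                                        cfg.slab_jitter_deg))
            c, s = np.cos(th), np.sin(th)
            ry = c * (yy[k] - cy) - s * (xx[k] - cx) + cy
            rx = s * (yy[k] - cy) + c * (xx[k] - cx) + cx
            src_y[k] = ry + (src_y[k] - yy[k]) + dty / voxel_size
            src_x[k] = rx + (src_x[k] - xx[k]) + dtx / voxel_size
    out = map_coordinates(labels, [src_z, src_y, src_x], order=0,
                          mode="constant", cval=0)
    return out.astype(labels.dtype)


def gmm_render(labels: np.ndarray, cfg: GenConfig,
               rng: np.random.Generator | None = None):
    """Sample a synthetic intensity volume from per-label univariate Gaussians.

    One (mean, variance) pair per label is drawn from the configured ranges
    each call; voxel intensities are sampled independently and clamped to
    [0, clip_max].  Returns ``(image, drawn_params)`` where ``drawn_params``
    maps label -> (mean, variance).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = np.asarray(labels)
    present = np.unique(labels)
    missing = [int(l) for l in present if int(l) not in cfg.label_params]
    if missing:
        raise errors.MissingLabelParams(f"no Gaussian ranges for {missing}")
    img = np.zeros(labels.shape, dtype=float)
    drawn = {}
    for lab in present:
        (mlo, mhi), (vlo, vhi) = cfg.label_params[int(lab)]
        mu = rng.uniform(mlo, mhi)
        var = rng.uniform(vlo, vhi)
        drawn[int(lab)] = (mu, var)
        sel = labels == lab
        img[sel] = mu + np.sqrt(var) * rng.standard_normal(int(sel.sum()))
    np.clip(img, 0.0, cfg.clip_max, out=img)
    return img, drawn


def _ap_window_average(img: np.ndarray, voxel_size: float,
                       centers_mm: np.ndarray, thickness: float) -> np.ndarray:
    """Average the volume over AP box windows (partial-volume weights)."""
    Z = img.shape[0]
    plane_z = (np.arange(Z) + 0.5) * voxel_size
    low = np.empty((len(centers_mm),) + img.shape[1:])
    for k, c in enumerate(centers_mm):
        lo, hi = c - thickness / 2.0, c + thickness / 2.0
        overlap = (np.minimum(plane_z + voxel_size / 2.0, hi)
                   - np.maximum(plane_z - voxel_size / 2.0, lo))
        w = np.clip(overlap, 0.0, voxel_size)
        tot = w.sum()
        if tot <= 0:
            nearest = int(np.clip(round(c / voxel_size - 0.5), 0, Z - 1))
            low[k] = img[nearest]
        else:
            low[k] = np.tensordot(w / tot, img, axes=(0, 0))
    return low


def simulate_training_pair(labels: np.ndarray, voxel_size: float,
                           cfg: GenConfig,
                           rng: np.random.Generator | None = None):
    """Full generative pipeline: one (input image, target labels) pair.

    deform -> per-label Gaussian rendering -> digital slicing at a random
    thickness (with per-slice variation) -> per-slice bias field +
    brightness/contrast/gamma -> resampling of the anisotropic stack back to
    the isotropic output grid.  The target is the deformed label map on that
    same grid; image and target shapes are identical.

    Returns ``(image, target, info)`` with the drawn thickness and Gaussian
    parameters in ``info``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dlab = deform_labels(labels, voxel_size, cfg, rng)
    img, drawn = gmm_render(dlab, cfg, rng)
    img = img / cfg.clip_max  # normalized [0, 1] from here on

    Z, Y, X = img.shape
    extent = Z * voxel_size
    T = rng.uniform(*cfg.thickness_range_mm)
    n_low = max(int(np.floor(extent / T + 1e-9)), 1)
    centers = (np.arange(n_low) + 0.5) * T
    if cfg.thickness_variation_mm > 0:
        centers = centers + rng.uniform(-cfg.thickness_variation_mm,
                                        cfg.thickness_variation_mm, n_low)
    low = _ap_window_average(img, voxel_size, centers, T)

    v = voxel_size
    for k in range(n_low):
        if cfg.bias_amplitude > 0:
            gfield = smooth_log_field((Y, X), cfg.bias_amplitude,
                                      cfg.bias_smoothness_mm / v, rng)
            low[k] = low[k] * np.exp(gfield)
        b = rng.uniform(*cfg.brightness_range)
        c = rng.uniform(*cfg.contrast_range)
        gmm_ = rng.uniform(*cfg.gamma_range)
        low[k] = np.clip(c * low[k] + b, 0.0, 1.0) ** gmm_

    r = cfg.output_resolution_mm
    out_shape = (max(int(round(extent / r)), 1),
                 max(int(round(Y * v / r)), 1),
                 max(int(round(X * v / r)), 1))
    oz = ((np.arange(out_shape[0]) + 0.5) * r) / T - 0.5
    oy = ((np.arange(out_shape[1]) + 0.5) * r) / v - 0.5
    ox = ((np.arange(out_shape[2]) + 0.5) * r) / v - 0.5
    gz, gy, gx = np.meshgrid(oz, oy, ox, indexing="ij")
    image = map_coordinates(low, [gz, gy, gx], order=1, mode="nearest")
    hz = ((np.arange(out_shape[0]) + 0.5) * r) / v - 0.5
    tz, ty, tx = np.meshgrid(hz, oy, ox, indexing="ij")
    target = map_coordinates(dlab, [tz, ty, tx], order=0, mode="nearest")
    info = {"thickness_mm": float(T), "gaussians": drawn,
            "n_low_slices": int(n_low)}
    return image, target.astype(labels.dtype), info
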