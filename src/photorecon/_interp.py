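"""Linear interpolation kernels with exact analytic spatial gradients.

The joint reconstruction objective is optimized with a quasi-Newton method, so
every resampling step must expose the derivative of the sampled value with
respect to the (continuous) sampling coordinate.  scipy's ``map_coordinates``
does not return such gradients, hence these small vectorized kernels.

Convention: samples outside the source footprint decay linearly to zero over
one pixel/voxel (the source is conceptually embedded in an infinite zero
background), which keeps the sampled function continuous and piecewise linear
everywhere.
"""

from __future__ import annotations

import numpy as np


def bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray,
             grad: bool = False):
    """Sample ``img`` at float coordinates (rows, cols).

    Returns ``vals`` or ``(vals, d_drow, d_dcol)`` when ``grad`` is True.
    Coordinates are in pixel units with (0, 0) the center of the first pixel.
    """
    H, W = img.shape
    pad = np.zeros((H + 2, W + 2), dtype=float)
    pad[1:-1, 1:-1] = img

    # shift into padded frame; clamp so r0 in [0, H], r0+1 <= H+1
    r = np.clip(np.asarray(rows, dtype=float) + 1.0, 0.0, float(H))
    c = np.clip(np.asarray(cols, dtype=float) + 1.0, 0.0, float(W))
    clip_r = (rows + 1.0 != r)
    clip_c = (cols + 1.0 != c)

    r0 = np.minimum(np.floor(r).astype(np.intp), H - 0)
    c0 = np.minimum(np.floor(c).astype(np.intp), W - 0)
    fr = r - r0
    fc = c - c0

    v00 = pad[r0, c0]
    v10 = pad[r0 + 1, c0]
    v01 = pad[r0, c0 + 1]
    v11 = pad[r0 + 1, c0 + 1]

    vals = (v00 * (1 - fr) * (1 - fc) + v10 * fr * (1 - fc)
            + v01 * (1 - fr) * fc + v11 * fr * fc)
    if not grad:
        return vals
    d_dr = (v10 - v00) * (1 - fc) + (v11 - v01) * fc
    d_dc = (v01 - v00) * (1 - fr) + (v11 - v10) * fr
    # clamped coordinates: function constant there, derivative zero
    d_dr = np.where(clip_r, 0.0, d_dr)
    d_dc = np.where(clip_c, 0.0, d_dc)
    return vals, d_dr, d_dc


def trilinear(vol: np.ndarray, zi: np.ndarray, yi: np.ndarray, xi: np.ndarray,
              grad: bool = False):
    """Sample 3D ``vol`` at float voxel coordinates (zi, yi, xi).

    Returns ``vals`` or ``(vals, d_dz, d_dy, d_dx)``.
    """
    Z, Y, X = vol.shape
    pad = np.zeros((Z + 2, Y + 2, X + 2), dtype=float)
    pad[1:-1, 1:-1, 1:-1] = vol

    z = np.clip(np.asarray(zi, dtype=float) + 1.0, 0.0, float(Z))
    y = np.clip(np.asarray(yi, dtype=float) + 1.0, 0.0, float(Y))
    x = np.clip(np.asarray(xi, dtype=float) + 1.0, 0.0, float(X))
    clip_z = (zi + 1.0 != z)
    clip_y = (yi + 1.0 != y)
    clip_x = (xi + 1.0 != x)

    z0 = np.floor(z).astype(np.intp)
    y0 = np.floor(y).astype(np.intp)
    x0 = np.floor(x).astype(np.intp)
    fz = z - z0
    fy = y - y0
    fx = x - x0

    c000 = pad[z0, y0, x0]
    c100 = pad[z0 + 1, y0, x0]
    c010 = pad[z0, y0 + 1, x0]
    c001 = pad[z0, y0, x0 + 1]
    c110 = pad[z0 + 1, y0 + 1, x0]
    c101 = pad[z0 + 1, y0, x0 + 1]
    c011 = pad[z0, y0 + 1, x0 + 1]
    c111 = pad[z0 + 1, y0 + 1, x0 + 1]

    w000 = (1 - fz) * (1 - fy) * (1 - fx)
    w100 = fz * (1 - fy) * (1 - fx)
    w010 = (1 - fz) * fy * (1 - fx)
    w001 = (1 - fz) * (1 - fy) * fx
    w110 = fz * fy * (1 - fx)
    w101 = fz * (1 - fy) * fx
    w011 = (1 - fz) * fy * fx
    w111 = fz * fy * fx

    vals = (c000 * w000 + c100 * w100 + c010 * w010 + c001 * w001
            + c110 * w110 + c101 * w101 + c011 * w011 + c111 * w111)
    if not grad:
        return vals

    d_dz = ((c100 - c000) * (1 - fy) * (1 - fx) + (c110 - c010) * fy * (1 - fx)
            + (c101 - c001) * (1 - fy) * fx + (c111 - c011) * fy * fx)
    d_dy = ((c010 - c000) * (1 - fz) * (1 - fx) + (c110 - c100) * fz * (1 - fx)
            + (c011 - c001) * (1 - fz) * fx + (c111 - c101) * fz * fx)
    d_dx = ((c001 - c000) * (1 - fz) * (1 - fy) + (c101 - c100) * fz * (1 - fy)
            + (c011 - c010) * (1 - fz) * fy + (c111 - c110) * fz * fy)
    d_dz = np.where(clip_z, 0.0, d_dz)
    d_dy = np.where(clip_y, 0.0, d_dy)
    d_dx = np.where(clip_x, 0.0, d_dx)
    return vals, d_dz, d_dy, d_dx
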