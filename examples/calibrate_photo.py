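"""Detect fiducial markers in a synthetic dissection-board photo, fit the
planar calibration and rectify the image.

Builds an 800x600 scene with four textured markers at the corners of a
100 x 80 mm rectangle, detects them by SIFT template matching, fits the
4-point perspective calibration and reports the pixel size and the residual
detection error (how far each detected marker center lies from where it was
pasted).
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from photorecon import (MarkerTemplate, RawPhoto, RectangleGeometry,
                        detect_fiducials, fit_calibration, rectify)


def make_marker(seed, size=56):
    r = np.random.default_rng(seed)
    m = gaussian_filter(r.uniform(0, 1, (size, size)), 1.5)
    m = (m - m.min()) / (m.max() - m.min())
    return (m * 255).astype(np.uint8)


markers = [MarkerTemplate(image=make_marker(s), name=f"corner{s}")
           for s in range(4)]
scene = np.full((600, 800), 30, dtype=np.uint8)
centers = [(100, 120), (110, 640), (480, 660), (470, 140)]
for mk, (r, c) in zip(markers, centers):
    h, w = mk.image.shape
    scene[r - h // 2:r - h // 2 + h, c - w // 2:c - w // 2 + w] = mk.image

photo = RawPhoto(pixels=scene)
fid = detect_fiducials(photo, markers, RectangleGeometry(width_mm=100,
                                                         height_mm=80))
truth = np.array([(r - 28 + 27.5, c - 28 + 27.5) for r, c in centers])
err = np.linalg.norm(fid.points - truth, axis=1)
print("detected marker centers (row, col px):")
for name, pt, e in zip("ABCD", fid.points, err):
    print(f"  {name}: ({pt[0]:7.2f}, {pt[1]:7.2f})   error {e:.2f} px")

cal = fit_calibration(fid)
rect = rectify(photo, cal, target_pixel_size=0.2)
print(f"calibration mode: {cal.mode}")
print(f"suggested pixel size: {cal.pixel_size:.4f} mm/px")
print(f"rectified image: {rect.pixels.shape} at {rect.pixel_size} mm/px")
print("-> sub-2-pixel detections mean the homography maps the board onto a")
print("   true millimetric grid; all later measurements are in mm.")
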