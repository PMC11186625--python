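"""Reading and writing of the standard file formats used by the pipeline.

Photographs: PNG/JPEG/TIFF (8/16 bit) via imageio.  Masks: PNG (0/255) or
NIfTI.  Volumes: NIfTI via nibabel.  Meshes: PLY/STL/OBJ via trimesh.
Transforms, ordering specs and simulation ground truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import trimesh

from .photo_prep import RawPhoto, SliceOrdering
from .recon_core import ReconstructedVolume, ReconstructionParams
from .synth_sim import SimulatedStack, SliceStack, StackTruth


def load_photo(path) -> RawPhoto:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return RawPhoto(pixels=arr, metadata={"file": str(path)})


def save_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        return (np.asarray(nib.load(path).dataobj) > 0).astype(np.uint8)
    return (iio.imread(path) > 0).astype(np.uint8)


def load_volume(path):
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(path)
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)


def save_reconstruction(path, vol: ReconstructedVolume) -> None:
    """Write the reconstructed intensity volume as NIfTI (RAS affine)."""
    # axes (n, r, c) with the affine already mapping to RAS
    save_volume(path, vol.intensity, vol.affine)


def load_mesh(path) -> trimesh.Trimesh:
    return trimesh.load_mesh(path)


def save_params(path, params: ReconstructionParams) -> None:
    obj = {"mode": params.mode,
           "phi": [list(map(float, p)) for p in params.phi],
           "s": params.s, "sigma": params.sigma,
           "psi": list(map(float, params.psi))}
    Path(path).write_text(json.dumps(obj, indent=2))


def load_params(path) -> ReconstructionParams:
    obj = json.loads(Path(path).read_text())
    return ReconstructionParams(phi=np.asarray(obj["phi"], dtype=float),
                                sigma=float(obj["sigma"]),
                                psi=np.asarray(obj["psi"], dtype=float),
                                mode=obj["mode"])


def load_ordering(path) -> list[dict]:
    """Load a declarative slice-ordering spec.

    Format: ``{"photos": [{"file": str, "order": "anterior_first" |
    "posterior_first", "slices": [[component ids...], ...]}]}``.
    """
    obj = json.loads(Path(path).read_text())
    out = []
    for ph in obj["photos"]:
        out.append({"file": ph["file"],
                    "ordering": SliceOrdering(order=ph["order"],
                                              slices=ph["slices"])})
    return out


def save_simulated_stack(outdir, sim: SimulatedStack) -> None:
    """Write a simulated stack as PNG slices + masks + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    st = sim.stack
    lo, hi = st.images.min(), st.images.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    for n in range(st.n_slices):
        iio.imwrite(outdir / f"slice_{n:03d}.png",
                    ((st.images[n] - lo) * scale).astype(np.uint16))
        save_mask_png(outdir / f"mask_{n:03d}.png", st.masks[n] >= 0.5)
    truth = {"transforms": sim.truth.transforms.tolist(),
             "z_mm": sim.truth.z_mm.tolist(),
             "indices": sim.truth.indices.tolist(),
             "voxel_size": sim.truth.voxel_size,
             "pixel_size": st.pixel_size,
             "nominal_thickness": st.nominal_thickness,
             "intensity_scale": [float(lo), float(hi)]}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def load_simulated_stack(indir) -> SimulatedStack:
    indir = Path(indir)
    truth = json.loads((indir / "truth.json").read_text())
    imgs, msks = [], []
    lo, hi = truth["intensity_scale"]
    for f in sorted(indir.glob("slice_*.png")):
        imgs.append(iio.imread(f).astype(float) / 65535.0 * (hi - lo) + lo)
    for f in sorted(indir.glob("mask_*.png")):
        msks.append((iio.imread(f) > 0).astype(float))
    stack = SliceStack(images=np.stack(imgs), masks=np.stack(msks),
                       pixel_size=truth["pixel_size"],
                       nominal_thickness=truth["nominal_thickness"])
    st_truth = StackTruth(transforms=np.asarray(truth["transforms"]),
                          z_mm=np.asarray(truth["z_mm"]),
                          indices=np.asarray(truth["indices"]),
                          voxel_size=truth["voxel_size"])
    return SimulatedStack(stack=stack, truth=st_truth)
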