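"""Digitally slice a hemisphere phantom, perturb every slice, and recover the
3D volume by joint slice-to-volume reconstruction against the surface mask.

Prints the mean voxel displacement (mm) before and after reconstruction and
the recovered anterior-posterior scale.  The displacement is measured against
the known ground-truth pose of every simulated slice, after removing the
irrelevant common rigid pose.
"""

import numpy as np

from photorecon import (ReconstructionParams, ReferenceVolume, SlicingConfig,
                        digitally_slice, make_phantom, reconstruct,
                        reconstruction_error)

phantom = make_phantom()
print(f"phantom: {phantom.labels.shape} voxels at {phantom.voxel_size} mm")

# cut every 4 voxels (2.8 mm slabs) with per-slice rigid perturbations and
# illumination fields, as a dissection photograph simulator would
cfg = SlicingConfig(spacing=4, translation_mm=5.0, rotation_deg=10.0,
                    log_scale=0.0, shear=0.0, illumination_amplitude=0.15,
                    drop_empty=True, seed=7)
sim = digitally_slice(phantom.intensity, phantom.mask, phantom.voxel_size, cfg)
print(f"simulated stack: {sim.stack.n_slices} slices, "
      f"{sim.stack.nominal_thickness:.2f} mm nominal thickness")

ref = ReferenceVolume(volume=phantom.mask, voxel_size=phantom.voxel_size,
                      kind="surface_mask")
before = reconstruction_error(
    ReconstructionParams.identity(sim.stack.n_slices), sim)
result = reconstruct(sim.stack, ref, mode="surface")
after = reconstruction_error(result, sim)

print(f"objective: {result.objective_trace[0]:.4f} -> "
      f"{result.objective_trace[-1]:.4f} over {len(result.objective_trace)} "
      "iterations")
print(f"mean voxel displacement: {before:.2f} mm unregistered -> "
      f"{after:.2f} mm reconstructed "
      f"({100 * (1 - after / before):.0f}% reduction)")
print(f"recovered anterior-posterior scale s = {result.params.s:.4f}")
print("-> sub-voxel displacement means each photographed slice was put back")
print("   where it was cut from; the stack is ready for 3D volumetry.")
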