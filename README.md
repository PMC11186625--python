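# photorecon

**3D reconstruction and quantitative analysis of brain dissection
photographs.**

Brain banks photograph coronal slices of dissected specimens as a matter of
routine, but those photographs are rarely used quantitatively. `photorecon`
turns a stack of 2D dissection photographs into a calibrated, 3D-reconstructed
volume suitable for volumetry, and provides the simulation and statistical
machinery to validate every step on synthetic data with known ground truth.
It is aimed at neuroimaging/neuropathology researchers who want morphometry
from photographs when ex vivo MRI is unavailable.

The package has four parts:

* **`photo_prep`** — fiducial detection (SIFT template matching), 2/3/4-point
  planar calibration (pixel size + perspective correction), tissue
  segmentation, and grouping of connected components into ordered slices.
* **`recon_core`** — joint slice-to-volume registration. With per-slice
  planar transforms Φₙ, an anterior–posterior scale *s* and a reference pose
  Ψ, it maximizes

  F = α·D(M, R∘Ψ) + β·(1/(N−1))Σₙ C(Sₙ, Sₙ₊₁) + γ·(1/(N−1))Σₙ D(Mₙ, Mₙ₊₁) − ν·(1/N)Σₙ |log det Φₙ|

  where D is the soft Dice overlap between the assembled slice masks M and
  the reference R (a rasterized surface scan, or a probabilistic atlas), C a
  mask-weighted normalized cross-correlation between consecutive slices, and
  the last term penalizes in-plane scaling/shear. Optimization is L-BFGS
  with hand-derived analytic gradients (defaults: surface mode α=.95,
  β=γ=.025, ν=γ/100; atlas mode α=.8, β=γ=ν=.1).
* **`synth_sim`** — a hemisphere phantom generator, a digital-slicing
  simulator (spacing, thickness jitter, per-slice affine distortion,
  illumination fields, full ground-truth poses), the mean-displacement error
  metric, and the domain-randomized generative process for segmentation
  training data (label deformation → per-label Gaussian rendering → slicing →
  bias/intensity augmentation → isotropic resampling).
* **`evaluation`** — 2D Dice, label volumes, GLM covariate correction,
  AUROC + Wilcoxon rank-sum group comparison, Pearson validation
  correlations, and Steiger tests for dependent correlations.

## Worked example

`examples/reconstruct_phantom.py` slices a synthetic hemisphere phantom into
2.8 mm slabs, perturbs every slice by a random rigid motion (up to ±5 mm,
±10°) plus an illumination field, and reconstructs the stack against the
phantom's surface mask:

```
$ python examples/reconstruct_phantom.py
phantom: (64, 64, 64) voxels at 0.7 mm
simulated stack: 13 slices, 2.80 mm nominal thickness
objective: 0.9344 -> 0.9503 over 443 iterations
mean voxel displacement: 3.85 mm unregistered -> 0.50 mm reconstructed (87% reduction)
recovered anterior-posterior scale s = 0.9692
-> sub-voxel displacement means each photographed slice was put back
   where it was cut from; the stack is ready for 3D volumetry.
```

The displacement numbers compare every foreground voxel's recovered position
with its known ground-truth position (common rigid pose removed): the
perturbed, unregistered stack is off by ~3.9 mm on average; after joint
reconstruction the residual is ~0.5 mm — below the 0.7 mm voxel size. The
recovered scale *s* ≈ 1 confirms the nominal slice thickness was close to
correct in this simulation.

The other examples are narrative too: `calibrate_photo.py` (fiducial
detection and perspective calibration), `synthesize_training_data.py` (one
domain-randomized training pair), `group_statistics.py` (covariate-corrected
AUROC/rank-sum statistics and a Steiger test).

A thin CLI mirrors the pipeline stages:

```bash
photorecon simulate --spacing 4 --jitter 0.2 --seed 7 --out stack/
photorecon reconstruct --stack-dir stack/ --reference surf.ply --mode surface --out recon.nii.gz
photorecon evaluate groupstats --table volumes.csv --out stats.csv
```

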