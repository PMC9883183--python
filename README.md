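# isletseg

Segmentation and 3-D volumetric quantification of pancreatic islets in
phase-contrast micro-CT slice stacks.

Islets of Langerhans appear in reconstructed synchrotron phase-contrast
tomography slices as compact, slightly brighter inclusions — a few
dozen µm across at 7.8 µm voxel pitch — on a textured background full
of look-alikes (vessels, exocrine tissue), and they occupy well under
1% of the pixels.  `isletseg` is for researchers who want to go from a
stack of grayscale slices to per-islet counts, volumes and size
distributions:

1. **Segmentation** — AA-Net, a U-Net-shaped encoder–decoder whose
   encoder mixes shortcut-free (SF) double-conv blocks with residual
   blocks, and whose bottleneck is an affinity-aware attention module:
   with bottleneck pixels flattened to N columns, `W = QᵀK` scores every
   pixel pair, `A = softmax_row(W)`, and `H′[c,i] = Σⱼ A[i,j] V′[c,j]`
   lets every pixel's feature draw on all others before the decoder
   restores resolution.  Training uses the class-weighted cross-entropy
   `L_w = Σᵢ [α(−tᵢ log pᵢ) + (1−α)(−(1−tᵢ)log(1−pᵢ))]` with
   `α = |t₋|/(|t₊|+|t₋|)`, plus an explicit L2 term `L_r`, and keeps the
   checkpoint with the best validation F-score.
2. **Reconstruction** — per-slice connected components are stitched
   across neighbouring slices whenever their centroids lie within
   γ = 5 px (strictly), closed transitively; volume = voxels × 7.8³ µm³.
3. **Phantoms** — a generator of synthetic stacks (drifting bright
   ellipsoids, vessel-like tubes, textured noise, exact voxel-count
   manifests) so the whole pipeline is testable without scan data.

The network and its training loop run on a small NumPy reverse-mode
autodiff engine included in the package; no GPU or deep-learning
framework is required.

## Worked example

Generate a phantom and quantify its truth masks
(`examples/04_quantify_islets.py`):

```
true islets: 10, recovered: 10
volumes recovered exactly: 10/10
        0-     25 x10^3 um^3: 0 islets
       25-    100 x10^3 um^3: 0 islets
      100-    500 x10^3 um^3: 4 islets
      500-   1500 x10^3 um^3: 6 islets
  >= 1500 x10^3 um^3: 0 islets
```

All ten 3-D islets are recovered with voxel-exact volumes — with
centroid drift below γ and islets separated by more than 2γ, stitching
truth masks is lossless — and the histogram is the size distribution
used to compare cohorts (large islets being the class most sensitive to
diabetic damage).

Training the scaled-down network on ~300 balanced 64×64 phantom patches
(12 epochs, base 8 channels, a couple of minutes on one CPU) and
segmenting a held-out phantom stack
(`examples/03_train_and_segment.py`) prints:

```
training patches: 310, foreground fraction 0.015
best validation F-score 0.863 at epoch 12
held-out stack: SE 0.997  PPV 0.743  IOU 0.741  F 0.852  AUPR 0.984
```

SE near 1 with PPV ≈ 0.74 says nearly all true islet pixels are found
with some false positives at islet rims and vessels; F = 0.852
summarises the overlap and AUPR the threshold-free ranking quality.

## Command line

The same stages are exposed as subcommands:

```
isletseg --seed 1 phantom --shape 64 256 256 --n-islets 15 --out scan
isletseg preprocess --stack scan_image.tif --mask scan_mask.tif --out patches
isletseg train --patches patches.npz --epochs 12 --lr 1e-3 --out ckpt
isletseg predict --stack scan_image.tif --checkpoint ckpt --out pred
isletseg evaluate --probs pred_prob.tif --truth scan_mask.tif --out report
isletseg quantify --masks pred_mask.tif --gamma 5 --pitch-um 7.8 --out islets
```

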