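# smart3d

Segmentation and spatial quantification of 3D tissue-cleared, multi-channel
fluorescence volumes — built for tumor-microenvironment morphometry in
brain-metastasis imaging, where whole cleared samples are stained for tumor
cells (K8), astrocytes (GFAP), proliferating nuclei (EdU), all nuclei
(DAPI) and vasculature, and every question is a spatial one: how
proliferative is each metastasis, how much reactive astrogliosis surrounds
it, and how far is each tumor voxel from the nearest blood vessel?

The pipeline:

1. **Background removal** — percentile filtering with a window slightly
   larger than the smallest object estimates the inhomogeneous
   autofluorescence field; a one-class model flags blocks where objects
   larger than the window corrupted the estimate; flagged blocks are
   re-interpolated and the refined field subtracted.
2. **Voxel classification** — per channel and scale σ, the features
   {intensity, gradient magnitude, Hessian eigenvalues, structure-tensor
   eigenvalues} are concatenated across channels into a multi-channel
   feature vector (MFV); one random forest per class (200 trees, 2
   candidate features per split) labels every voxel; accuracy is the F1
   score of 10-fold cross-validation.
3. **Structural segmentation** — connected tumor components above a volume
   threshold (or containing K8 signal, regardless of size) become tumor
   clusters with physical volumes in μm³.
4. **Quantification** — per cluster: proliferative index
   |EdU ∩ T| / |T|; gliosis index = astrocyte fraction of the 24 μm
   surrounding shell (dilate spherically by *dis* = 24 μm, subtract the
   cluster); concentric 10 μm zone profiles inward to the core or outward
   into the niche; per-voxel closest distances to vessels with their
   Gaussian-KDE mode; intratumoral and peritumoral (≤100 μm) mean vascular
   density.
5. **Statistics** — size classes on log₁₀ volume (large > 5.0), per-class
   Gaussian KDEs, quadratic regression of proliferative index vs log₁₀
   volume, two-sided variance F-tests, Pearson correlations.

A synthetic phantom generator (`smart3d.phantom`) renders full scenes —
lobular tumors, tortuous vessels, partial astrocyte shells, per-zone EdU
placement, inhomogeneous background, mixed noise — with exact ground truth,
so the entire pipeline is testable without microscopy data. Distances and
volumes are anisotropy-aware throughout (μm, never voxels).

## Worked example

```python
import numpy as np
from smart3d import (PhantomSpec, generate_phantom, segment_structures,
                     quantify_cluster)
from smart3d.phantom import sample_training_labels
from smart3d.pipeline import (PipelineParams, preprocess, extract_mfv,
                              train_classifiers, classify_all)
from smart3d.classify import ForestConfig

spec = PhantomSpec(seed=11)                      # 72³ scene, two tumors
mcv, truth = generate_phantom(spec)

params = PipelineParams(forest=ForestConfig(seed=11),
                        volume_threshold_um3=500.0)
cleaned = preprocess(mcv, params)                # background removal
mfv = extract_mfv(cleaned, params)               # 120-feature MFV

rng = np.random.default_rng(11)                  # 1% expert-style labels
labels = {c: sample_training_labels(truth.masks[c], 0.01, rng)
          for c in ("tumor", "astrocyte", "proliferating", "vessel")}
masks = classify_all(train_classifiers(mfv, labels, params), mfv)

for cl in segment_structures(masks["tumor"], 500.0):
    rec = quantify_cluster(cl, masks["proliferating"], masks["astrocyte"],
                           masks["vessel"])
    print(f"tumor {rec.tumor_id}: V={rec.volume_um3:.0f} μm³ "
          f"prolif={rec.proliferative_index:.3f} "
          f"gliosis={rec.gliosis_index:.3f}")
```

Output:

```
tumor 1: V=5463 μm³ prolif=0.187 gliosis=0.405
tumor 2: V=4913 μm³ prolif=0.177 gliosis=0.406
```

The phantom was built with proliferative index 0.15 and astrocyte shell
coverage 0.40; the recovered volumes are within ~2% of the true 4847 and
5362 μm³, gliosis within 0.01 of its target, and the proliferative index
within the expected classification margin of its target.

## Command line

`smart3d` exposes `phantom`, `remove-bg`, `train`, `classify`, `segment`,
`quantify`, `stats`, `align` and `run` (full pipeline from one YAML
config); every command writes a provenance record (config hash, seed,
version) next to its outputs. Example:

```sh
smart3d phantom --out-dir scene/ --seed 3
smart3d remove-bg --in scene/GFAP.tif --out gfap_clean.tif \
        --window 9 --percentile 20 --spacing 1,1,1
smart3d quantify --tumors clusters.tif --edu edu.tif --gfap gfap.tif \
        --vessels vessels.tif --zone-um 10 --gliosis-um 24 \
        --peritumoral-um 100 --out quant.csv
```

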