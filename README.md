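# nodemorph

Segmentation and morphometric classification of lymph nodes on CT
images.  Radiologic assessment of nodal metastasis from size alone is
unreliable — benign and malignant nodes overlap in diameter — but shape
and internal structure (spiculation, heterogeneity) carry diagnostic
signal.  `nodemorph` provides the full image-to-prediction chain for
researchers working on quantitative nodal staging:

1. **Denoising** — an edge-enhanced nonlinear diffusion
   `u_t = μ div(g(|∇G_σ0∗u|)∇u) − (|∇u|/max|∇u|)(u−I)` that removes
   noise in flat regions while the gradient-weighted fidelity term pins
   edges to the data, plus the standard baselines (Perona–Malik, TV/ROF,
   median, bilateral) and Canny edge extraction.
2. **Segmentation** — a parametric snake driven by gradient vector flow
   (GVF), with a *repulsive force*: the external field is negated outside
   the region R enclosed by the user's initial contour
   (`v⁻ = v` in R, `−v` otherwise), so the curve cannot leak onto
   adjacent bright structures.
3. **Classification** — a 19-feature morphometric panel per node
   (including boundary fractal dimension, solidity, axis diameters,
   nodal density, heterogeneity), pruned by backward–forward
   permutation-importance selection driven by the consistency loss
   `|P(S₁)−P(S₂)| + 2|Q(S₁)−Q(S₂)|` (P accuracy, Q sensitivity), and an
   SVM evaluated with leave-one-out cross-validation.

A synthetic-data module generates phantoms, adjacency scenes, noisy
shape images, and labeled feature tables with exact ground truth for
testing and benchmarking.  See `docs/methods.md` for the models and
numerical choices.

## Worked example

Segment a noisy synthetic node and classify a labeled feature table:

```python
import numpy as np
from nodemorph import (PhantomSpec, SelectionConfig, TableSpec,
                       add_gaussian_noise, edge_enhanced_diffusion,
                       extract_features, initialize_contour, loocv,
                       make_feature_dataset, make_node_phantom, segment,
                       select_features)

image, true_mask = make_node_phantom(
    PhantomSpec(shape="spiculated", irregularity=0.4, size_px=40,
                heterogeneity_sd=5.0), seed=7)
noisy = add_gaussian_noise(image, snr_db=15.0, seed=7)
denoised = edge_enhanced_diffusion(noisy)

init = initialize_contour(center=(50.0, 50.0), radius=27.0, n_points=100)
contour, mask = segment(denoised, init, repulsive=True)
feats = extract_features(denoised, mask)
print(f"dice vs truth: "
      f"{2 * (mask & true_mask).sum() / (mask.sum() + true_mask.sum()):.3f}")
print(f"fractal dimension: {feats['fractal_dimension']:.3f}, "
      f"solidity: {feats['solidity']:.3f}")

X, y = make_feature_dataset(TableSpec(n_samples=200, informative=(0, 1, 2),
                                      effect_size=2.0, seed=0))
state = select_features(X, y, SelectionConfig(seed=0))
print(f"selected {len(state.active_features)} features, "
      f"LOOCV accuracy {loocv(X, y, state.active_features).accuracy:.3f}")
```

Output:

```
dice vs truth: 0.917
fractal dimension: 1.000, solidity: 0.956
selected 17 features, LOOCV accuracy 0.935
```

The segmented mask overlaps the generating region at Dice 0.917 (the
snake smooths over the finest spicules, which also lowers the measured
irregularity of the *segmented* region relative to the generating mask);
selection keeps the three informative columns plus noise columns whose
removal the stopping rule could not justify, and the resulting
classifier separates the classes at 93.5% LOOCV accuracy.

The same stages are scriptable from the shell:

```bash
nodemorph simulate shapes --snr-db 9.46 --seed 0 --out-dir scene/
nodemorph denoise --method edge_enhanced --in scene/image.tif --out den.tif
nodemorph segment --in den.tif --seed 32,38,26 --out-mask mask.png \
    --out-contour contour.csv
nodemorph features --image den.tif --mask mask.png --out features.csv
```

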