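# mamseg

Level-set segmentation of mass lesions in digital mammograms, and a toolkit
for quantifying how sensitive the resulting shape descriptors are to where
the initial contour is placed.

Mass margins in direct digital mammography are often embedded in overlying
tissue: boundary information goes missing and interior low-signal areas act
as local minima that can trap an evolving contour.  Region-based active
contours therefore produce different segmentations depending on where the
initial contour starts — and any shape descriptors computed from the final
boundary inherit that variability.  `mamseg` implements:

- **weighted total-variation scale-space smoothing** — gradient descent on
  `E(I) = ∫ g|∇I| + λ|I − I₀|`, with edge indicator
  `g = 1/(1 + γ|∇G_θ∗I₀|²)`, so noise is removed while mass edges survive;
- **iso-level search space** — the smoothed image is thresholded with
  equally spaced levels `T = I_max·W`; the sub-level regions
  `R(t) = {(x,y) : I_S ≤ t}` nest, and a dense band of nested iso-level
  contours localizes the mass boundary;
- **a proposed semi-automatic initial contour** — radial lines cast from
  the centre of the innermost band contour; on each ray the crossing with
  maximum gradient gives a radius `rᵢ`, and outliers
  (`rᵢ ≥ r_ave + n·r_std`, n = 1 or 2) are clipped back to the mean radius;
- **two evolution models** — the Chan-Vese piecewise-constant model
  (`∂φ/∂t = δ_ε(φ)[μ κ − ν − λ₁(I−c₁)² + λ₂(I−c₂)²]`, defaults μ = 0.2,
  λ₁ = 2.5, λ₂ = 1) and the selective local/global signed-pressure-force
  model (`∂φ/∂t = α·spf(I)·|∇φ|` with binarization and Gaussian
  regularization of φ, default α = 5);
- **shape descriptors** of the final mask: boundary moments
  `F₁ = √μ₂/m₁`, `F₂ = μ₄^{1/4}/m₁`, `F₃ = |F₁ − F₂|`, 60 Fourier
  descriptors `FD_i = |a_i|/|a_0|` of the centroid distance function,
  shape convexity (area / convex-hull area) and shape rectangularity
  (area / minimum-area enclosing rectangle);
- **agreement metrics**: Jaccard overlap, absolute percentage differences
  `%Δ = |b − a|/mean(a,b) × 100`, Euclidean distance between
  Fourier-descriptor vectors, Bland-Altman limits of agreement and
  Pearson/linear regression;
- **synthetic phantoms** with ground truth for the two margin classes
  (distinct vs obscured/ill-defined with interior low-signal areas), so the
  whole pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
from mamseg import (PhantomSpec, make_phantom, make_manual_init,
                    proposed_initial_contour, segment, describe,
                    compare_pair, jaccard)

ph = make_phantom(PhantomSpec.ill_defined(seed=3))     # 208x208 phantom

# initialization A: proposed radial max-gradient contour
init_a = proposed_initial_contour(ph.image, lam=0.05)
mask_a, _, stats, _ = segment(ph.image, init_a, model="chanvese")

# initialization B: loose manually-drawn-style enclosing contour
init_b = make_manual_init(ph.truth_contour, dilation=12, shape=ph.image.shape)
mask_b, _, _, _ = segment(ph.image, init_b, model="chanvese")

pair = compare_pair(mask_b, mask_a, describe(mask_b), describe(mask_a))
print(f"JSC={pair.jsc:.3f}  DF={pair.df:.4f}  %dF1={pair.pd_f1:.1f}")
print(f"JSC vs truth (proposed init) = {jaccard(ph.truth_mask, mask_a):.3f}")
```

prints

```
JSC=0.655  DF=0.1694  %dF1=132.8
JSC vs truth (proposed init) = 0.646
```

On this heavily blurred phantom the two initializations land in different
local minima: the segmented areas overlap with a Jaccard coefficient of
only 0.66 and the first boundary moment differs by 133% — boundary moments
amplify initialization differences.  Sharp-margin phantoms behave in the
opposite way (JSC ≈ 0.99, %ΔF₁ below a few percent); the margin class, not
the model, drives initialization sensitivity.  Cohort means over ten
phantoms per class are what `scripts/acceptance.py` reports.

The same pipeline is available from the shell:

```sh
mamseg phantom --margin ill_defined --seed 3 --out img.tif --truth truth.png
mamseg smooth --lam 0.05 --out smoothed.tif img.tif
mamseg init --n-sigma 1 --rays 360 --out init.csv smoothed.tif
mamseg segment --model chanvese --init init.csv --out mask.png img.tif
mamseg describe --out descriptors.csv mask.png
mamseg compare --x truth.png --y mask.png --out pair.json
mamseg experiment --model spf --n-per-class 10 --out cohort.csv
```

## Layout

| module | role |
|---|---|
| `mamseg.preprocess` | weighted TV flow, edge indicator, scale space |
| `mamseg.isolevel` | thresholds, iso-level contour map, nesting, search band |
| `mamseg.initcontour` | radial profile, clipping rule, initial contour |
| `mamseg.evolve` | Chan-Vese and SPF evolution, level-set utilities |
| `mamseg.shapedesc` | centroid distance, moments, FDs, convexity, rectangularity |
| `mamseg.metrics` | Jaccard, %Δ, DF distance, Bland-Altman, regression |
| `mamseg.phantoms` | synthetic phantom generator, sensitivity experiment |
| `mamseg.pipeline` / `mamseg.cli` / `mamseg.io` | composition, CLI, formats |

See `docs/methods.md` for the models, numerical choices and limitations.
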