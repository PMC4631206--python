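# cytocode

Single-cell cytometry analysis of an epithelial apoptosis **signaling
code** — a reusable, tested pipeline for asking: *which combination of
signaling markers distinguishes the cells of a tissue that are dying from
the ones that survive?*

The motivating system is the murine small-intestinal epithelium under acute
TNF-α challenge, where only a subset of villus enterocytes undergoes
caspase-dependent apoptosis while their neighbors activate a p-ERK survival
program.  The package is aimed at cytometry/systems-biology analysts who
want that style of analysis — mass-cytometry gating, supervised linear
discrimination, permutation-based feature selection — as composable Python
rather than a GUI workflow, and who need every stage testable without any
animal-derived data.  A synthetic-cohort generator with planted ground truth
stands in for the instrument.

## What it computes

Events × channels intensities **X** (arcsinh-transformed, debris/doublet
gated, restricted to the enterocyte call) and a binary response *y*
(cleaved-caspase-3 positive = dying) are fit with 2-latent-variable **PLS
discriminant analysis** (NIPALS PLS1 on the class indicator after
autoscaling).  With weights **W**, loadings **P**, response loadings **q**,
the per-channel discriminant coefficients are

> β = W (PᵀW)⁻¹ q

Classifier quality is the ROC AUC of the score xᵀβ, on the calibration set
and pooled over 10%-holdout cross-validation (random, venetian-blind and
contiguous-block folds).  Feature selection runs two ways and is required to
agree:

* **Permutation null** — refit on B label permutations; pⱼ =
  (1 + #{|β⁽ᵇ⁾ⱼ| ≥ |βⱼ|}) / (B+1); take the top-k smallest p.
* **VIP scores** — VIPⱼ = √( p·Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ ),
  mean(VIP²) ≡ 1, keep VIP > 1.

The selected markers are combined *without rescaling* into a per-cell score
Σⱼ sⱼ xⱼ (sⱼ = sign βⱼ), the "signaling code".  Companion modules provide
t-SNE embedding with density-contour population gating (lowest-density
decile excluded), a hexagonal-lattice neighbor-survival simulation
(expected activated:dying ratio (1−p)(1−(1−p)⁶)/p), cross-platform
time-course Z-scoring and Pearson correlation, and nuclear/cytoplasmic-ring
image quantification.

## Worked example

```python
from cytocode.pipeline import RunConfig, run

report = run(RunConfig(seed=1, B=1000))
print(report["calibration_auc"])      # 0.9634
print(report["cv_auc"])               # {'random': 0.9625, 'venetian': 0.9623, 'block': 0.9624}
print(report["selected_features"])    # ['p-P38', 'p-CREB', 'p-ERK', 'CK20']
print(report["selector_agreement"])   # True
print(report["combined_auc"])         # 0.9519
print(report["single_marker_aucs"])   # {'p-P38': 0.893, 'p-CREB': 0.886,
                                      #  'p-ERK': 0.105, 'CK20': 0.190}
```

Reading these numbers: on a simulated 5,000-event cohort the 2-LV model
separates dying from living enterocytes with AUC 0.96, and cross-validation
matches the calibration AUC to the third decimal — the hallmark of a model
with far more events than parameters.  Both selectors recover exactly the
four planted code markers (p-P38↑, p-CREB↑, p-ERK↓, CK20↓; an AUC far
*below* 0.5 for p-ERK/CK20 means high values mark the survivors).  No
single marker separates the populations as cleanly as their unscaled sum.

The same stages are scriptable from a shell (`cytocode simulate | gate |
classify | embed | contour | train | crossval | permute | compare |
quantify-image | run`).

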