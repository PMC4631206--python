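# Methods

This note documents the models, conventions and design choices behind
`cytocode`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The discriminant model

The core statistic is PLS1 regression of a binary class indicator
(living = 0, dying = 1) on the analyte channels, used as a linear
classifier (PLSDA).  Channels are mean-centered and, by default, scaled to
unit sample variance (ddof = 1) — the chemometrics autoscaling convention,
which puts ion-count channels of very different dynamic range on one
footing.  With a single response, each NIPALS component is closed-form
(weight w ∝ Xᵀy, score t = Xw, loading p = Xᵀt/tᵀt, response loading
q = yᵀt/tᵀt, deflation X ← X − tpᵀ), so the fit is non-iterative and
deterministic; successive score vectors are mutually orthogonal by
construction and the fit refuses constant features (relative sd below
1e-12) rather than dividing by ~0.  Two latent variables are the default:
the discrimination problem is low-rank (one planted contrast plus
correlated identity structure), and the cross-validation results show no
benefit from more.

β = W(PᵀW)⁻¹q lives in the *scaled* space; predictions add the class-prior
intercept so the decision score is calibrated around the dying fraction.
At n_lv = rank(X) the fit provably collapses to ordinary least squares, and
the test suite holds the implementation to an independently coded
Krylov-subspace closed form (the PLS1 weight space is the Krylov space of
XᵀX applied to Xᵀy) at 1e-8, with scikit-learn's `PLSRegression` as a
second, independent cross-check of predictions.

**Which cells enter the model.**  The discriminant contrasts dying versus
living *enterocytes*.  Classifying first and restricting matters: if the
negative class is the whole living mixture, lineage markers (e.g. the
goblet marker CLCA1) become genuine discriminators — dying cells are all
enterocytes, so anything that separates enterocytes from secretory cells
predicts survival — and crowd out part of the true signaling code.  The
pipeline therefore types cells (precedence CD45 > CHGA > DCLK1 > CLCA1 >
CK18 > enterocyte, thresholds anchored at a control quantile) and fits on
the enterocyte call only.  CC3 itself is excluded from the predictors since
it defines the response.

## Inference on β

* **Permutation null**: B uniform label permutations, full refit each time,
  two-sided p with the +1 correction (p ∈ [1/(B+1), 1]); the per-feature
  null sd is reported for coefficient error bars.  B defaults to 10,000 for
  production runs; tests and the acceptance script use B = 500–1,000, which
  already puts the p floor (10⁻³) well past any selection threshold used.
  Under a null cohort the p-values are uniform (KS-tested in the suite).
* **VIP**: VIPⱼ = √(p Σₐ SSYₐ(wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ) with
  SSYₐ = qₐ²·tₐᵀtₐ; mean(VIP²) = 1 is an algebraic identity and is asserted
  on every fitted model, so VIP > 1 marks above-average importance.
* **Selection**: top-k by permutation p (ties by |β|, then channel order)
  and the VIP > 1 set, with an explicit agreement flag.  The combined score
  Σ sign(βⱼ)·xⱼ is deliberately *not* z-scored: it is meant to be computable
  on a new sample from transformed channel values alone, with no model
  constants.

## ROC and cross-validation

AUC is the normalized Mann–Whitney U with ties counted ½ (average ranks);
the suite pins it to a brute-force concordant-pair count, including heavy
tie cases.  Cross-validation withholds 10% per fold under three schemes —
shuffled folds, venetian blinds (every 10th event at successive offsets, in
file order), contiguous blocks — refits per fold and pools held-out scores
into a single cross-validated ROC.  Venetian/block folds are defined on
file order with no pre-shuffle so they are reproducible and sensitive to
acquisition-order drift.  A fold whose training half lacks a class is
skipped with a warning and recorded; if skipping leaves one pooled class
the pooled AUC is NaN rather than fabricated.

## Synthetic cohorts

The generator emulates what the downstream analysis assumes about an
intestinal-epithelium mass-cytometry acquisition; its defaults are the
study conditions, not tuning knobs.

* **Mixture**: enterocyte 0.87, goblet 0.10, enteroendocrine 0.01, tuft
  0.01, leukocyte 0.01 — the published abundance scale for villus
  epithelium (goblet ≈ 10%, enteroendocrine ≈ 1%, tuft ≈ 1%).
* **Expression**: log-normal per channel (positive, right-skewed, the
  standard stand-in for ion counts), baseline exp(N(ln 10, 0.5²)), each
  population's own lineage markers elevated by +2.5 log-units.
* **Planted code**: a dying subset of enterocytes (default fraction 0.10;
  the acute-TNF duodenum preset uses ⅓, the observed kill fraction) carries
  +2.5 log-units of CC3 and ±1.0 log-units (2 sd) on p-P38 (+), p-CREB (+),
  p-ERK (−), CK20 (−).  Only the p-ERK direction (absent in dying cells) is
  reported in the source biology; the other three directions are modeling
  choices, configurable per effect.  A 2 sd shift gives a single-marker AUC
  of Φ(2/√2) ≈ 0.9214 in closed form, which the suite verifies empirically.
* **DNA/length**: DNA intercalator bimodal at 2n = 100 and 4n = 200
  (log-sd 0.08, 20% 4n), event length log-normal around 30.  Debris sits
  near 20 with broad spread; doublets are sums of two singlet draws
  (default 5%), so their DNA and length double naturally.
* **Spatial mode**: cells on an odd-r offset hexagonal lattice die
  independently with probability p; every surviving neighbor of a dying
  cell gains a p-ERK shift (default 1.5 log-units) — the "flower petal"
  geometry.  For interior cells E[activated]/E[dying] =
  (1−p)(1−(1−p)⁶)/p exactly (inclusion–exclusion over six neighbors);
  boundary cells see fewer neighbors, so `observed_lattice_ratio` restricts
  to the interior by default.  The formula's small-p supremum is 6 — an
  isolated death activates exactly its six neighbors — and it sweeps the
  empirically reported 1:4.6–1:6 band as p grows.
* **Seeding**: one top-level seed fans out to per-operation substreams via
  `SeedSequence.spawn`; identical (spec, seed) → bit-identical cohorts.

What the generator does **not** emulate: mass-cytometer physics (ion-cloud
fusion, spillover, Gaussian-discriminator residuals), bead normalization or
batch drift, correlated signaling networks beyond the planted contrast, and
real biological covariance between lineage and signaling channels.  Passing
tests therefore certify the *procedure* — gating, fitting, selection,
calibration — not instrument-level robustness.

## Event processing conventions

* **Transform**: asinh(x/5) on analyte channels only, applied at most once
  (state-guarded); DNA/length stay raw for gating.
* **Debris/doublet gate**: DNA window [2n − 2·MAD*, 4n + 2·MAD*] with
  MAD* = 1.4826·MAD estimated around each location; 2n is the DNA-channel
  mode (median-refined within the modal histogram bin) and 4n is pinned at
  2×2n, the DNA-doubling constraint.  A plain 2-means location estimate was
  tried first and is not robust: with ≥10–15% debris the low center is
  dragged into the debris cloud and the window swallows it.  For samples
  that may lack an intact-cell mode entirely (debris-dominated tubes), pass
  control-anchored `dna_2n`/`dna_4n`.  The doublet cutoff is
  median + 3·MAD* of the event-length channel.  Gates are pure functions of
  (events, params) and record their thresholds.
* **Positivity thresholds**: quantile (default 0.99) of a vehicle-control
  sample, linear interpolation between order statistics (numpy default) —
  on {1..100} the 0.99 quantile is 99.01.  Note linear interpolation
  commutes with monotone transforms only at exact order statistics; between
  them the discrepancy is bounded by the local curvature and is orders of
  magnitude below any gating decision.
* **CSV dialect**: comma, header required, UTF-8, '.' decimal.  FCS support
  is a deliberately small built-in codec (float32 list mode, little-endian,
  one TEXT segment) covering what this package writes plus the common
  instrument profile.
* **Ground truth**: simulated cohorts carry hidden truth columns
  (population, dying/debris/doublet flags, lattice coordinates) in a
  sidecar only — never in FCS/CSV event output.

## Embedding and contour gating

t-SNE (perplexity 30, 1,000 iterations, PCA init, fixed seed) on all
analyte channels by default; the contract tested is determinism and
neighborhood preservation (10-NN label agreement on separable data), not
any particular coordinate layout.  Population gating estimates a Gaussian
KDE (Silverman bandwidth, full covariance — hence rotation/translation
equivariant) at each event, excludes the lowest-density 10% (an exact
count, ties broken by stable sort), thresholds the density surface at the
boundary value on a 256×256 raster, and labels 8-connected components;
retained events inherit their grid cell's component, with a
nearest-labeled-cell fallback for events whose cell rasterizes just under
the threshold.  With exclusion = 0 there is no contour to draw and the
plane is one region.  The per-event density is held, in tests, to a
brute-force pairwise-kernel oracle at machine precision.

## Time-course comparison

Each (platform, analyte, region, experiment) series is Z-scored — mean
centered, scaled by the sample sd (n−1) — after averaging replicates per
time point (configurable).  Platform aggregation conventions: cytometry →
median event intensity; immunoblot → integrated band intensity minus a
straight-line background between the bounding-box edges; imaging → mean
pixel intensity within the compartment mask.  Correlation matches pairs on
(analyte, region, time), drops unmatched points (never imputes), keeps
outliers, and reports per-analyte Pearson r with t-distribution p (n−2 df)
plus a combined analysis pooling all matched Z-scored pairs.  When both
platforms report a shared latent signal plus independent noise of variance
σ², the pooled r attenuates to 1/(1+σ²) — the closed form the acceptance
check recovers at σ² = ⅓ (r = 0.75).

## Image quantification

Nuclear masks: global Otsu threshold on the DNA channel (polarity flag for
inverted contrast), hole filling, removal of objects under 20 px,
8-connected counting.  The cytoplasmic ring is
dilate(nuclei, offset+thickness) \ dilate(nuclei, offset) with Euclidean
disk structuring elements, so every ring pixel lies at distance
(offset, offset+thickness] = (5, 7] px from the nearest nuclear pixel —
verified against a brute-force distance transform on every test image.
Rings clip at image borders and never intersect nuclei.  Positive-cell
fractions and co-localization are pixel counts normalized to the nuclear
mask area.  The fixture generator places non-overlapping disk nuclei,
paints a marker-positive subset, and in flower-petal mode paints the
survival signal on the rings of dying nuclei, so ring/center disjointness
is a constructed ground truth.

## Numerical and degenerate-input policy

Errors are raised early and name the offender: single-class fits, constant
features under autoscaling, zero-variance DNA, flat time courses, empty
masks and empty controls, unknown channels in effect specs.  Quantile
convention, tie-breaks (stable sorts; |β| then channel order in selection)
and the +1 permutation correction are frozen and documented above.  Sizes
used by the default test/acceptance runs — 5,000-event cohorts, B = 1,000
permutations, 100×100 lattices, 200 matched correlation pairs — were chosen
as the smallest scales at which the Monte-Carlo checks have comfortable
margins over their standard errors.

## Known limitations

No multi-class PLSDA, sparse/regularized PLS, bead normalization,
debarcoding, batch correction, spillover modeling, or cell segmentation
beyond nuclei + ring.  The embedding contract does not reproduce any
specific external t-SNE implementation's coordinates.  Real acquisitions
violate the generator's independence assumptions in ways the suite cannot
certify; conclusions about real tissue require real controls.
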