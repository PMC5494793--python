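# Methods

`mammocad` implements a texture-based computer-aided-diagnosis pipeline for
mammogram regions of interest (ROIs): preprocessing, a 108-dimensional
feature ensemble, and hierarchical (one-/two-/three-stage) classification of
breast tissue density and health status, evaluated with micro-averaged
confusion-matrix metrics. This note records the model, the parameters that
matter, the numerical conventions, and the deliberate design choices.

## Preprocessing

Each ROI is histogram-equalized, then filtered with non-local means (NLM).

**Histogram equalization.** `out(v) = round((L-1)·cdf(v))` with `L = 2^bit_depth`
and `cdf` the empirical cumulative histogram over all `L` levels. Exact `.5`
ties round *down* (so a two-level 8-bit image with cdf 0.5/1.0 maps to
127/255). The mapping is monotone, hence idempotent up to rounding. 16-bit
inputs equalize over 65536 levels at native scale; there is no automatic
rescale to 8-bit.

**NLM.** `NL[v](i) = Σ_j w(i,j)·v(j)` with
`w(i,j) ∝ exp(−‖v(N_i)−v(N_j)‖²_{2,σ}/h²)`, weights normalized to sum to 1.
The patch distance is a Gaussian-weighted (σ, kernel normalized to unit sum)
squared difference over the similarity patch. The sum over `j` is restricted
to a square search window — the standard tractable approximation of the sum
over the whole image. Borders are handled by reflect padding so the output
keeps the ROI size. Defaults (all CLI-configurable): `patch_radius=3` (7×7
patch), `search_radius=10` (21×21 window), `h=10` on the 8-bit scale,
`σ=1.0`. These are conventional NLM settings; nothing in the method fixes
them, and no fast-NLM approximations are used. The vectorized filter is
tested against the definitional per-pixel weight computation.

Note that equalization deliberately removes the global-brightness cue
(every image ends up spanning the full range), so downstream class signal
must come from texture, local shape and sub-band energy distribution — this
is visible in the synthetic experiments below.

## Wavelet decompositions (db1/Haar, orthonormal)

Two transforms are computed from the preprocessed image, both with
orthonormal db1 filters (PyWavelets, periodization mode):

* a **one-level 2D-DWT** into `{LL, LH, HL, HH}` — the four textures on
  which the LCP descriptor is computed;
* a **two-level full quad split**: each level-1 band is split again, giving
  the 16 bands `LLLL … HHHH`. (A pyramidal two-level DWT would give 7 bands;
  the 16-band wavelet-packet-style split is the variant whose band count and
  names match the feature layout used here.) The 16 **band energies**
  (sums of squared coefficients, LLLL first) form the frequency-domain
  feature block.

Odd dimensions are edge-replicated to even before each split. For unpadded
inputs the transform conserves energy to machine precision (padding adds
energy by construction, so the conservation tests use dimensions divisible
by 4).

## Local configuration patterns (LCP)

For every interior pixel, `P=8` neighbors are sampled on a circle of radius
`R=2` (angle origin on the +column axis, counterclockwise with rows growing
downward; off-grid positions bilinearly interpolated). With
`u(x) = 1 for x ≥ 0`, the bits `u(g_i − g_c)` give the rotation-invariant
uniform LBP code: popcount if the circular bit string has ≤ 2 transitions,
else the non-uniform code `P+1`. The local variance `VAR` is the population
variance of the 8 neighbor intensities.

Per uniform group `k ∈ {0..8}`:

* **MiC part** — the least-squares weights `A` minimizing
  `Σ_m (g_c^(m) − Σ_i A_i g_i^(m))²` over the group's pixels (minimal-norm
  solution via SVD; empty or all-zero systems give zeros), encoded as the
  8 DFT magnitudes `H = |FFT(A)|`, which are exactly invariant to circular
  rotation of the neighbor set;
* **occurrence part** `O_k` — the sum of `VAR` over the group's pixels
  (an LBPV-style joint LBP/VAR accumulation that keeps the descriptor at one
  occurrence entry per group; `occurrence="count"` switches to plain counts).

Flattening `[H_0;O_0;…;H_8;O_8]` gives 81 values per sub-band; non-uniform
pixels are excluded. The last entry — `O_8`, the occurrence of the all-ones
pattern, dominant in smooth images — is truncated, and the four 80-vectors
are fused by the weighted sum with coefficients `{LL:1.4, LH:1, HL:1, HH:0}`.
The HH descriptor is still computed so alternative weights need no code
change. Sub-bands are not renormalized before thresholding (the LBP
threshold is shift/scale covariant).

## Statistics and ensemble assembly

From the fused 80-vector `X` (length `N`): energy `ΣX²`, mean, variance
(`1/(N−1)`), max, min, std, skewness `Σ(X−μ)³/σ³` and kurtosis
`Σ(X−μ)⁴/σ⁴` — kept in the *unnormalized* printed form without the `1/N`
factor (a `standard_moments` flag restores the textbook normalization),
area descriptor `σ/μ`, mean energy, energy variance
`Σ(X²−μ_E)²/(N−1)`, and entropy `−Σ p log₂ p` with
`p_i = max(X_i,0)/Σ max(X_j,0)` and `0·log 0 := 0`. Degenerate conventions:
`σ=0 ⇒` skew=kurt=0, `μ=0 ⇒` area=0, all-zero `X ⇒` entropy=0 — every input
yields a finite vector.

The 108-vector is `[80 fused LCP | 12 statistics | 16 band energies]`.
Images must be at least 32×32 so the level-1 bands retain an LCP interior.

## Classification

**FLDA** (implemented here): projection maximizing
`J(w) = (wᵀS_B w)/(wᵀS_W w)` via the generalized symmetric eigenproblem
`(S_B, S_W)`, keeping the top `C−1` directions; a test point gets the class
of the nearest projected class mean. Features are standardized internally —
the decision rule is affine-invariant, so this is purely a conditioning
measure (the 108 features span ~8 orders of magnitude) — and `S_W` carries a
relative ridge of 1e−6 against exact singularity.

**Other kinds** (scikit-learn): shared-covariance linear discriminant,
linear-kernel SVM, multinomial logistic regression ("logistic linear
classifier"), CART decision tree, 100-tree random forest with majority
voting, Gaussian naive Bayes, and kNN with Euclidean distance and `k=5`
(`k` must not be a multiple of the class count). Stochastic kinds take an
explicit seed.

**Cross-validation**: stratified k-fold (default `k=11`) over the 12-way
tissue×health class, seeded and deterministic; per-class fold sizes differ
by at most one (233 members → nine folds of 21 and two of 22). A described
90/10 split of 233 per class (210/23) is arithmetically inconsistent with
elevenfold CV (11×23 = 253 ≠ 233); the honest stratified fold sizes above
are used instead.

**Cascades.** All schemes emit a final 3-class health label per sample and
are scored on the same 3×3 confusion matrix accumulated over folds:

* *one-stage*: direct health classification;
* *two-stage*: 4-class tissue classification, then a per-tissue health
  classifier;
* *three-stage*: tissue, then per-tissue normal-vs-abnormal screening, then
  benign-vs-malignant for abnormal-routed samples.

Branch models are trained on **truth**-grouped training samples (the
standard cascade convention) and applied along **predicted** routes, so
upstream errors propagate exactly as they would in deployment. A branch
whose training group is empty falls back to the fold's global one-stage
model (counted and reported); a single-class training group yields a
constant predictor. For the two- and three-stage schemes the three
classifiers with the highest overall CV accuracy (ranking recomputed, not
hard-coded) are combined by per-sample majority voting; a three-way
disagreement resolves to the top-ranked classifier's label.

## Evaluation

Nine metrics (SNS, SPC, PPV, NPV, FPR, FNR, FDR, FOR, ACC) from one-vs-rest
counts. The default pooling is **micro-averaging** — TP/FP/FN/TN summed over
classes before the formulas — under which SNS = PPV and SPC = NPV
identically; ACC is the plain multi-class accuracy trace/total, which
coincides with micro SNS/PPV. This is the convention that reproduces the
published one-stage metric-table pattern exactly. Macro-averaging
(unweighted per-class mean, zero-actual classes excluded with a warning) is
provided for comparison. Display rounding is half-up to 2 decimals; full
precision is kept internally.

## Synthetic phantoms

The published clinical ROI dataset (12 BI-RADS classes: 4 tissue densities ×
{normal, benign, malignant}, 233 ROIs each, 2796 total) is not
redistributable, so the package ships a seeded phantom generator producing
the same 12-class directory layout:

* **tissue** — base intensity mean {80, 110, 140, 170} (8-bit) and Gaussian
  random-field correlation length {6, 5, 4, 3} px for fatty → extremely
  dense (denser = brighter and finer-grained); the field is Gaussian-blurred
  white noise rescaled to std 5 — with the fixed +30 lesion contrast this
  makes lesions salient (6× texture std) but, after equalization, noise and
  taper keep the classes overlapping rather than trivially separable;
* **health** — normal: no lesion; benign: additive circular blob of radius
  ≈ size/6 with a linear taper from +30 at the center to 0 at the border;
  malignant: the same taper over a star-shaped region with 8–14 spicules
  and rough angular modulation;
* additive Gaussian noise (σ=4), values clipped to [0, 255], default 64×64,
  per-image seeds derived from a master seed (byte-identical re-runs).

The phantoms emulate class-conditional brightness/texture/shape structure
only; they do not model pectoral muscle, compression, scanner noise or
calcifications. Passing the pipeline smoke test therefore shows that the
implementation extracts and classifies the injected class signal — it says
nothing about clinical accuracy, and the published clinical accuracies
(85.47 / 88.79 / 93.52 % for the one-/two-/three-stage schemes) are not
reproducible from synthetic data.

## Problem sizes and verification

The test suite and the acceptance script verify, among others: the printed
one-stage confusion matrix reproduces its printed metric row to 2 decimals;
descriptor/ensemble dimensionalities (81/80/108/16); 2796-record dataset
structure and 21–22 CV fold sizes; riu2 against an exhaustive 256-pattern
rotation-minimization oracle; NLM weight normalization (1e−9) and filter
convexity; db1 energy conservation (1e−6 relative, 100 random unpadded
images); exact MiC rotation invariance; the 12 statistics against an
independent re-implementation (1e−9 relative, 1000 vectors); majority
voting against an exhaustive 162-case oracle; and a full-pipeline run —
12 classes × 30 phantoms, 108-dim features, one-stage FLDA, stratified
2-fold hold-out — that must exceed 60% health accuracy against a 33.3%
chance level (observed 67–76% across seeds). The 12×30 scale and the 2-fold
split keep the smoke run at about a minute while leaving ~180 held-out
samples; results are insensitive to the master seed.

## Known limitations

* The 81-element LCP layout (9 groups × (8 magnitudes + 1 occurrence)) is
  reconstructed from dimensional arithmetic; alternative layouts with the
  same length exist.
* NLM parameters are conventions, not values fixed by the method.
* Published two- and three-stage metric tables are internally inconsistent
  under every standard averaging convention tried and are not used as
  fixtures; only the one-stage table is.
* Phantom realism is deliberately minimal (see above).
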