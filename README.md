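# mammocad

Texture-based computer-aided diagnosis (CAD) for mammogram regions of
interest (ROIs). The package is aimed at medical-image-analysis researchers
who want a complete, testable reference implementation of a classical
hand-crafted-feature CAD pipeline: local-configuration-pattern (LCP) texture
descriptors on wavelet sub-bands, a statistical/spectral feature ensemble,
and hierarchical cascade classification of breast tissue density (BI-RADS
style) and health status.

## The method

Each grayscale ROI is histogram-equalized and denoised with non-local means
(NLM),

&nbsp;&nbsp;NL[v](i) = Σⱼ w(i,j)·v(j),&nbsp;&nbsp;
w(i,j) ∝ exp(−‖v(Nᵢ)−v(Nⱼ)‖²₂,σ / h²),

then decomposed with the orthonormal Haar (db1) wavelet. On each level-1
sub-band {LL, LH, HL, HH} the LCP descriptor is computed with P = 8
neighbors at radius R = 2: per rotation-invariant uniform LBP group, the
8 DFT magnitudes |H| of the least-squares weights A reconstructing the
center pixel from its neighbors (the MiC part), plus a local-variance-
weighted occurrence O — 9 groups × 9 values = 81 entries, truncated to 80
and fused across sub-bands with weights {1.4, 1, 1, 0}. Twelve statistics of
the fused vector (energy, mean, variance, extrema, σ, skewness, kurtosis,
σ/μ, mean energy, energy variance, entropy) and the 16 sub-band energies of
a two-level full wavelet split complete the 108-dimensional feature vector

&nbsp;&nbsp;x = [80 LCP | 12 statistics | 16 energies].

Classification runs as a one-stage (3-class health), two-stage (tissue →
per-tissue health) or three-stage (tissue → normal/abnormal →
benign/malignant) cascade under stratified 11-fold cross-validation, with
eight classifiers (Fisher LDA implemented from first principles; LDC, linear
SVM, logistic linear, decision tree, random forest, naive Bayes, kNN via
scikit-learn) and top-3 majority voting. Confusion matrices are scored with
micro-averaged sensitivity/specificity/predictive-value metrics, under which
SNS = PPV = ACC and SPC = NPV identically.

A seeded phantom generator emulates the 12-class (4 tissue × 3 health)
ROI-dataset layout so the whole pipeline runs without any clinical data.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

```bash
mammocad synth roi --per-class 4 --seed 7       # 48 phantoms, 12 classes
mammocad extract roi -o features.csv            # 48 x 108 feature table
mammocad run --features features.csv --scheme 2 --folds 2 --seed 7 \
    --classifiers flda,ldc,naive_bayes,knn -o report.json
```

The report contains, per classifier, the 3×3 health confusion matrix
accumulated over folds and its micro-averaged metrics. For this tiny run the
two-stage FLDA cascade reaches 64.58 % health accuracy (chance = 33.3 %):

```
flda 64.58   ldc 47.92   naive_bayes 31.25   knn 37.50
top3 voting (flda, ldc, knn): 60.42
flda confusion: [[11, 3, 2], [1, 12, 3], [2, 6, 8]]
flda micro:     SNS 64.58  SPC 82.29  PPV 64.58  NPV 82.29  ACC 64.58
```

Rows/columns are (normal, benign, malignant): 11 of 16 normal phantoms are
recognized, and the micro-averaged identities SNS = PPV = ACC are visible
directly. Accuracies climb well above this at realistic sample sizes
(per-class 30 gives ~67–76 % one-stage FLDA accuracy).

The metric engine can also be used standalone on any printed confusion
matrix, e.g. the total one-stage confusion matrix of a logistic linear
classifier over 3036 ROIs:

```bash
$ mammocad metrics 862 91 59 123 889 0 166 2 844
SNS 85.47  SPC 92.74  PPV 85.47  NPV 92.74
FPR  7.26  FNR 14.53  FDR 14.53  FOR  7.26  ACC 85.47
```

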