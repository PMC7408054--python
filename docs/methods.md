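# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Optical model and phantoms

A-lines follow a single-scattering Beer–Lambert model in linear intensity,
`I(z) = I₀ exp(−2 μ Δ z)` with round-trip attenuation `μ` (mm⁻¹) and axial
pixel `Δ` (default 1 µm, the order of the emulated system's sub-micron
axial resolution; configurable). Speckle is modelled as multiplicative
unit-mean exponential intensity noise — the fully-developed-speckle
statistics of coherent intensity imaging. The per-depth mean over many
realizations equals the noiseless envelope (verified to 3% at 10⁴
realizations), which is why ROI estimation averages A-lines *before*
estimating: the per-voxel estimate on raw speckle is exponentially
distributed around the truth, and its median would sit near ln 2 ≈ 0.69 of
it. Confocal-gate and sensitivity roll-off envelopes are not modelled;
volumes are ideal exponentials above a flat noise floor.

Region attenuation presets come from the cohort medians for
tumor core / infiltration / parenchyma per entity (e.g. glioblastoma-like:
3.20 / 4.00 / 4.45 mm⁻¹; lower-grade-glioma-like: 2.90 / 2.95 / 4.35 mm⁻¹),
so "tumor" regions attenuate less, and simulated fluorescence is an
affine-decreasing function of local μ plus Gaussian noise — reproducing the
observed negative fluorescence–attenuation coupling at the generator level.

## Attenuation estimation

The per-voxel estimator is the depth-resolved single-scatter form
`μ[i] = I[i] / (2 Δ Σ_{j>i} I[j])`, applied per flattened A-line. Properties
used as oracles: it is scale-equivariant (a pure ratio), monotone in true μ
on noiseless exponentials, and equals `(e^{2μΔ}−1)/(2Δ)` to 1e−9 relative
when the tail sum is complete — the `e^{2μΔ}` factor is a +O(μΔ)
discretization bias, ≈ +0.3–0.5% at the defaults, far below the speckle
noise floor.

**Truncation guard.** The finite imaging depth truncates the tail sum and
inflates `μ[i]` by `1/(1 − e^{−2μΔ(n_z − i)})`. A fixed guard masking the
deepest 10% of samples is the per-voxel default, but at μΔ ≈ 0.003–0.004
that still leaves percent-level inflation over much of the column, and
under speckle the inflated deep values additionally bias the ROI *median*
upward by occupying the upper ranks. ROI profiles therefore apply an
adaptive second guard: a first-pass μ estimate from the shallowest valid
depths predicts the truncation per depth, and depths with predicted
truncation above 2% are masked (falling back to the shallowest quartile if
nothing would survive). ROI depth windows restrict which depths are
*reported*, never the tail sum itself. With this, the three cohort presets
are recovered within ~0.7% from 200 speckled A-lines, comfortably inside
the 5% recovery target. En-face projections use caller-chosen depth
windows; on speckled volumes use the `mean` reducer (unbiased under
unit-mean noise) and a window that keeps predicted truncation small.

**Surface detection.** The noise floor is 2× the 99th percentile of the top
5 axial pixels (assumed above tissue everywhere). Smoothing uses a trailing
(causal) 5-pixel axial window — a centered window would smear signal upward
and bias the surface shallow — and the first smoothed crossing is refined
to the first raw crossing within the window, then median-filtered 5×5
laterally. Re-detection on a flattened volume must reuse the original
volume's threshold (`noise_threshold`), since the flattened top rows
contain signal. Flattening shifts each column circularly and marks
wrapped-in voxels invalid; it is idempotent and leaves ≤1 px residual tilt
on speckled tilted phantoms.

## Fluorescence

Per-sample summaries are the ROI mean (median also reported; the convention
is not fixed in the field). Normalization is min–max over the *whole
dataset* — the minimum maps to 0 and the maximum to 1 — exactly as in the
emulated protocol; it is rank-preserving and idempotent but globally
coupled: adding a new dataset maximum rescales every other value downward,
so the bounds are stored alongside the values for reproducible
re-normalization. A per-image option is deliberately absent from the
default path. Transverse profiles average a 3-row band (mean, not max; the
reduction is unspecified in the emulated protocol) centered on the
requested row.

## H&E rendering, deconvolution, and counting

Rendering and unmixing share one stain matrix: the conventional published
H&E optical-density vectors (H ≈ [0.650, 0.704, 0.286],
E ≈ [0.072, 0.990, 0.105], residual = normalized cross product), rows
unit-normalized. Rendering is `RGB = 255·10^(−OD·S)` quantized to uint8;
deconvolution is `OD = −log10(max(RGB, ε)/255) · S⁻¹`. The two are mutual
inverses up to uint8 quantization: "in-gamut" mixes — every RGB channel OD
≤ 0.9, i.e. transmission at least ~8 quantization steps — round-trip within
0.01 OD (worst-case quantization analysis gives ≈ 0.0098 after unmixing);
darker mixes are limited by the 8-bit pixel, not the math.

Nuclei are uniform-OD ellipses (semi-axes 4–7 px at 0.5 µm/px, random
orientation), rejection-placed with pairwise center distance greater than
the sum of major semi-axes when overlap is forbidden (retry budget
100 × n). Uniform interiors make the OD round-trip at centroids exact to
quantization; real chromatin texture is not modelled.

Thresholding runs on the OD-scaled hematoxylin channel (nuclei bright)
after subtracting the slide-wide median H OD: nuclei are a minority of the
area, so the median estimates the background level, which then sits at
exactly zero and cannot pass the strict `> t` test — otherwise windows near
nuclei (local mean ≈ 0) would admit background halos. Phansalkar parameters
are the method's original ones (k=0.25, r=0.5, p=2, q=10, radius 15 px);
local moments use square windows with reflective boundaries, and the local
mean is clamped at 0 because the separable filter can return −1e−17 on flat
zero regions, which would flip the threshold's sign. Counting takes
connected components ≥ 20 px after a radius-1 opening, with
distance-transform watershed splitting (peak separation 5 px) for touching
nuclei. Density heatmaps use 50 µm tiles by default; partial edge tiles use
their true clipped area, making `Σ density·area = count` exact.

## B-scan classifier

Preprocessing: bilinear resize to 128×128 and per-image min–max to [0, 1]
(constant images map to zeros). The network is a sequential CNN — three
conv(3×3)/ReLU/max-pool(2×2) blocks with 8→16→32 filters, flatten, dense 64,
dropout 0.5, dense softmax — trained with Adam (1e−3, batch 16) on
categorical cross-entropy. The conv engine is implemented in numpy
(im2col + GEMM, exact hand-written gradients, finite-difference-checked in
the tests) and is fully seeded, so training is reproducible on a fixed
platform. Filter counts are a package choice sized for single-CPU training;
the block order, dropout 0.5 and Adam follow the emulated protocol, whose
published description fixes those but not the widths. `ModelConfig`
defaults to 100 epochs per that protocol; the package's own evaluation runs
(tests, acceptance, demo) train 8 epochs (`evaluation_config`), a
problem-size choice — the synthetic textures separate within a few epochs
and the loss curve is flat thereafter.

Synthetic B-scans: 36 patients (18 per class), one sample each, 6 B-scans
per sample (216 scans), mirroring the five-to-six-scans-per-patient cohort
structure; 3 patients per class are tagged as the held-out test split.
Tumor renders as fine-grained high-cellularity speckle with low μ
(3.20 ± 0.25 mm⁻¹ per sample), parenchyma as depth-layered coarse-grained
texture with high μ (4.45 ± 0.25). The optional infiltration class is
parenchyma carrying 0–5 small (16×16 px) tumor-texture patches — scant
tumor in normal tissue — so a fraction of infiltration scans is genuinely
indistinguishable from parenchyma; pooling them with tumor therefore
strictly lowers held-out accuracy, the qualitative analogue of the
two-class → pooled-infiltration accuracy drop seen on real data. No claim
is made that the synthetic textures match real OCM contrast; passing tests
show the *pipeline* (splitting, training, evaluation, leakage guards)
behaves correctly, not that real-world accuracy would be as high.

Cross-validation partitions *sample IDs*, shuffled by seed and split into k
validation groups, so scans of one biopsy never straddle a fold; evaluation
refuses test sets sharing any sample or patient with training. Metrics
come from the 0.5-threshold contingency table plus ROC/AUC on the
continuous score (scikit-learn). The nonsense test scores balanced
arbitrary labels on structureless uniform-noise images; any
label-independent predictor lands at chance (exactly 0.5 for a constant
predictor on a balanced set).

## Statistics

One-way ANOVA (scipy) with an explicit undefined-F guard (zero within-group
variance with equal means); verified against a brute-force sum-of-squares
oracle to 1e−12. Pairwise contrasts are Welch two-sample t-tests (tissue
variances differ) with Bonferroni adjustment `p_adj = min(1, m·p)`;
significance at 0.05. Spearman uses mid-ranks with the asymptotic p by
default and an exact pairing-permutation p for small n. Detection of the
glioblastoma-like parenchyma-vs-tumor gap (4.45 ± 0.99 vs 3.20 ± 0.76,
n = 10/group) is checked as statistical *power* over repeated cohorts
(> 0.5), consistent with that contrast being marginally significant at
cohort scale. Observations are treated as independent samples; the emulated
design pools several biopsies per patient without a hierarchical model —
a known limitation of the original analysis that this package reproduces
rather than fixes.

## Pipeline and reproducibility

`fioct run` derives one seed per stage from the master seed (SHA-256 of
`"{seed}:{stage}"`, kept below 2³¹), validates the config against a closed
schema before any stage executes, and writes a manifest with per-file
SHA-256 checksums; identical configs reproduce identical checksums. Demo
problem sizes (48×48×800 phantom, 120 nuclei, 10-patient dataset, 4
epochs) are chosen so a full run takes well under a minute; study-scale
parameters (deeper phantoms, 500-nucleus slides, the 36-patient dataset)
are what the test suite exercises.

## Known limitations

* The OCT forward model is single-scatter with ideal speckle; no multiple
  scattering, dispersion, polarization, confocal gating, or roll-off.
* Whether intensity should be focus/roll-off-corrected before estimation is
  an open question for imported real data; a dB→linear flag exists but no
  correction model.
* The adaptive truncation guard assumes a single dominant μ within the
  averaged ROI; strongly layered media would need per-layer fitting, which
  is out of scope.
* Nucleus morphology and stain texture are idealized; count-recovery
  numbers on phantoms are upper bounds on real-slide performance.
* Classifier determinism is per-platform (BLAS-dependent reduction order).
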