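# Methods

## Scope and assumptions

The package models *baseline* multi-modal data only: one time point per
patient, at most two imaging modalities (pathology, radiology), structured
(not free-text) reports, and a binary response target derived from RECIST
and PFS. Radiology is handled as 2-D lesion ROI slices with binary masks;
no DICOM ingestion, 3-D resampling or lesion segmentation is performed —
real masks must be supplied in the manifest. Target-lesion bookkeeping
follows RECIST v1.1: at most two lesions per organ, at most five in total,
enforced as manifest invariants.

## Outcome labelling

A patient is a responder when RECIST is CR/PR/SD **and** PFS strictly
exceeds the cohort threshold (8 months for anti-HER2 therapy and for the
external cohort, which received the same therapy; 10 months for anti-HER2 +
immunotherapy). "Exceeding" is read strictly: an event at exactly the
threshold month is a non-responder. CR/PR alone is not sufficient — a
CR/PR patient progressing at or before the threshold is a non-responder,
which keeps the definition a single consistent rule. Patients censored
before exceeding the threshold are excluded from response analysis but kept
in survival analysis.

## Architecture and defaults

Feature dimension d = 64 with 4 attention heads (head dim 16), word
embedding dim d_word = 32, gated-attention hidden width 32, predictor MLP
64→32→2. These are deliberately desk-scale — the architecture is the
object of study, not its capacity — and every width is configurable through
`FusionConfig`. The word backbone is a 4-block 3×3 stride-2 CNN trained
end-to-end; any feature extractor implementing `forward(Tensor) → Tensor`
can be plugged in instead (e.g. a pretrained lightweight CNN). The network
and its training run on a small in-package reverse-mode autodiff engine
over numpy (float64, CPU); gradient correctness is property-tested against
central finite differences.

Design choices where the design was genuinely open:

- **Modal-specific vs modal-agnostic split.** The agnostic map is *shared*
  across modalities while specific maps are per-modality: a shared map plus
  the contrastive alignment loss is the natural way to realise one
  modality-invariant embedding space.
- **Missing-modality placeholders.** The placeholder replaces the missing
  modality's *specific* slot in the fused layout
  `[path-specific | agnostic | rad-specific]`; the present modality's
  agnostic feature stands in for the average. Placeholders are ordinary
  parameters (init N(0, 0.1²)) and receive gradients exactly when their
  modality is absent in a batch.
- **Alignment loss.** Symmetric InfoNCE over cosine similarities,
  temperature 0.1, computed only over batch members with both modalities;
  an empty eligible set contributes 0.
- **Intra-modal query.** A single patient-level query vector (rather than a
  token set); with one image-derived K/V token the first cross-attention
  reduces to a learned transform of V, which the residual sum makes benign.
- **Report/patient-info tokens.** Each token carries its presence flag as an
  extra input column, so the attention can learn to discount absent fields;
  tokens of an absent report are all-zero with presence 0.
- **Risk orientation.** The score is P(non-response); "high-risk" means
  expected non-response and shorter survival.

## Training

Adam (lr 1e-3, β = 0.9/0.999), batch 16, 30 epochs by default (the bundled
experiments use 4–10 epochs; on the synthetic cohorts validation AUC
plateaus within a handful of epochs and longer schedules only overfit the
small training split). Class imbalance is handled by inverse-frequency
weights in the cross-entropy, normalised to mean 1. λ_align = 0.1. One full
parameter snapshot is kept per epoch with its validation AUC; the final
model is the parameter-wise mean of the top-7 snapshots (ties broken toward
the earlier epoch; fewer than 7 snapshots are averaged in full with a
warning). Training is bitwise-reproducible for a fixed seed on fixed data
up to BLAS associativity.

## Preprocessing

Pathology: Reinhard colour transfer in the decorrelated lαβ space (Ruderman
matrices, log10 domain); the target statistics are the mean over up to 64
training tiles' channel stats; a zero source σ is treated as 1 so constant
images map onto the target means; grey-world white balance follows.
Radiology: per-organ dynamic windows — percentile (0.5, 99.5) ranges of
training-split lesion voxels, cached to a JSON sidecar keyed by organ, with
a global fallback — applied as a linear map to [0, 1]. Tiling uses 0-based
half-open rectangles, bags 32 px with 16 px words; partial boundary bags
are discarded rather than padded.

Omics features are a fixed, named 20-vector: 11 first-order statistics
(entropy over 32 bins, log base 2), 5 shape features (perimeter is the
crack-edge length, so a filled s×s square has perimeter exactly 4s and
circularity π/4), and 4 GLCM statistics (32 grey levels, distance 1, four
directions with symmetric counts, statistics averaged over directions;
out-of-mask pixels are excluded via a sentinel level; GLCM energy is the
joint energy Σp²). Omics vectors are standardised with training-split
mean/std. Full radiomics libraries compute hundreds of features; this fixed
subset keeps the vector auditable against straight-line formula oracles.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the appearance of real H&E or CT data. Per patient a latent risk
z ~ N(0, 1) drives:

- pathology tiles (64×64 RGB): dark-nuclei density Poisson(8 + 22·σ(u)) and
  texture amplitude rising with u = effect_image·z;
- radiology lesions (32×32 + mask): ellipse radius and internal intensity
  heterogeneity rising with u; organ codes respect the RECIST caps;
- reports: P(peritoneal metastasis) = σ(−1.5 + effect_report·z); TIL level
  falls with effect_report·z; metastatic lymph-node counts rise mildly;
- patient info: differentiation and Lauren-type odds tilted by
  effect_info·z;
- outcomes: PFS ~ Exponential(rate = s·exp(r·z)) where r is the mean of the
  three effect strengths, so a zero-effect cohort is a *true null* (labels
  independent of z, and of everything the model sees); s is calibrated so a
  z = 0 patient exceeds the cohort PFS threshold with probability
  `base_response_rate` (0.5). OS adds an Exponential(mean 6 months) tail;
  an independent Exponential censoring clock at rate s/4 yields ≈ 20%
  censoring. RECIST categories come from logits linear in r·z (base
  CR/PR/SD/PD probabilities 0.10/0.35/0.35/0.20 at z = 0) — a smooth
  version of quartile-based assignment, chosen so the null genuinely
  decouples.

Reference conditions: 400 patients; availability fractions 0.45 both /
0.30 pathology-only / 0.25 radiology-only (fewer than half complete);
effect strengths (image, report, info) = (2.5, 2.0, 1.5), fixed once after
a ceiling analysis — at these values the AUC of z itself against the
realised labels is ≈ 0.92, i.e. the planted signal is strong but outcomes
remain stochastic; 4 bags of 4 words per pathology tile; 2 lesions per
patient. Realised responder labels and z go to a sidecar file that no
training code reads.

What the generator does **not** emulate: realistic histology/CT texture
families, scanner/centre batch effects, correlated missingness (modality
availability is independent of z), multi-lesion spatial context, or
informative censoring. Passing tests therefore demonstrate that the
pipeline recovers a planted multi-modal signal under the stated noise
model — not clinical performance on real cohorts.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½, via average ranks). The
bootstrap CI resamples patients (percentile 2.5/97.5, 2000 replicates;
single-class replicates redrawn up to 10 times, then skipped). The Youden
cutpoint maximises TPR − FPR over observed scores under "high-risk iff
score ≥ t", ties to the smallest t; thresholds learned on a validation
split should be frozen before application to any further split
(`evaluate_scores(threshold=...)`) to avoid leakage. Kaplan–Meier curves
and the Mantel–Cox log-rank test come from lifelines; the worked 4-subject
example is cross-checked against a hand-coded O−E/V oracle in the tests.
NNT is the reciprocal of the response-rate difference (low − high risk);
equal rates are reported as undefined, and an anti-predictive grouping
yields a negative value rather than being silently flipped.

## Problem sizes in the bundled experiments

The acceptance script and end-to-end tests use the reference cohort
(n = 400, 10/8 epochs) for planted-signal recovery, n = 240 replicates for
the null, and n = 160–200 complete-modality cohorts (4–5 epochs, 3–5 seeds)
for the fusion-vs-unimodal and missingness comparisons. These sizes were
chosen as the smallest at which the compared quantities are stable across
seeds; all are configurable.

## Known limitations

- The backbone is intentionally small; representation capacity, not fusion
  behaviour, will bound performance on real images.
- Float64 autodiff on CPU is exact but slow relative to GPU frameworks;
  cohorts beyond a few thousand patients need patience or a swapped
  backbone producing precomputed embeddings.
- The codebooks are package conventions (versioned YAML); real deployments
  must supply codebooks matching their report schemas.
- Survival handling assumes right-censoring only and a single PFS/OS pair
  per patient.
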