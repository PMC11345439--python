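# mumo — multi-modal treatment-response prediction

`mumo` predicts response to anti-HER2 (± immunotherapy) treatment in gastric
cancer from four heterogeneous sources: pathology tile images (bags of word
patches from whole-slide ROIs), radiology lesion ROI images with masks,
structured radiology/pathology reports, and baseline patient information. It
is aimed at researchers who want a fully testable, desk-scale implementation
of cross-attention multi-modal fusion with missing-modality handling — plus
the survival/stratification statistics used to judge such models — without
access to any clinical data: a built-in synthetic cohort generator plants a
known response signal in every modality.

## The model

Each modality is reduced to an image feature and a report token sequence:

- **Deep features.** Word patches are embedded by a small strided CNN and
  aggregated bottom-up (word → bag → patient) with gated-attention MIL
  pooling, `a_i ∝ exp(wᵀ(tanh(V h_i) ⊙ σ(U h_i)))`; bag-level attention
  weights double as interpretable importance scores.
- **Omics features.** A fixed 20-dimensional radiomics-style vector
  (first-order statistics, shape, GLCM texture) per masked region.
- **Parameterless encoders.** Reports and patient information are encoded by
  a versioned codebook: one token per field, one-hot/multi-hot/min-max slots,
  presence flags for missing values — no learned parameters.

Fusion proceeds in three stages. *Intra-modal*: the combined deep+omics
feature forms Q/K/V; one cross-attention merges the image information and a
second attends from Q over report-derived K′/V′, both added residually to
give `F_path`, `F_rad`. *Inter-modal*: each modal feature is split into a
modal-specific part (per-modality map) and a modal-agnostic part (shared
map); with both modalities present the fused feature is
`[F_path_s | mean(F_path_a, F_rad_a) | F_rad_s]` and a symmetric InfoNCE
loss over cosine similarities aligns the agnostic pair against in-batch
negatives; with one modality absent a **learnable placeholder** vector fills
its slot, so the 3d layout never changes. *Patient-information fusion*: a
query from the fused feature attends over the encoded patient-information
tokens; a softmax MLP outputs the risk score = P(non-response).

Training minimises class-weighted cross-entropy + λ·alignment, records one
checkpoint per epoch, and averages the weights of the top-7 checkpoints by
validation AUC. Evaluation reports Mann–Whitney AUC with a 2000-replicate
patient-level bootstrap CI, dichotomises risk by the Youden index, compares
the groups with Kaplan–Meier curves and the log-rank (Mantel–Cox) test, and
computes the number needed to treat, NNT = 1 / (response-rate(low-risk) −
response-rate(high-risk)).

Responder labels follow RECIST + survival: CR/PR/SD with PFS exceeding the
cohort threshold (8 months anti-HER2, 10 months combined immunotherapy) are
responders; PD, or observed progression at/below the threshold, are
non-responders; patients censored before the threshold are excluded from
response analysis but kept for survival analysis.

## Worked example

```python
from mumo import SimConfig, write_cohort, MuMoModel, TrainConfig

manifest = write_cohort(SimConfig(n_patients=200, seed=0), "cohort/")
res = MuMoModel.from_manifest(manifest).fit(
    train_config=TrainConfig(epochs=6, seed=0), val_fraction=0.25)
print(res.summary())
```

prints

```
Multi-modal treatment-response model
============================================
n train / n val       150 / 50
epochs                6
checkpoints averaged  6
n evaluated           44
AUC (non-response)    0.938
AUC 95% CI            (0.806, 1.000)
Youden threshold      0.243
log-rank chi2         16.171
log-rank p            0.0001
median PFS high-risk  2.3
median PFS low-risk   36.6
NNT                   1.12
NNT 95% CI            (1.00, 1.42)
```

The generated cohort plants a latent risk `z` in every modality (nuclei
density and texture in pathology tiles, lesion size/heterogeneity in
radiology, peritoneal metastasis and TIL level in reports) and links PFS/OS
to `z`; the model recovers it: validation AUC 0.938 on 44 labelled patients
(6 censor-excluded), the Youden cutpoint splits the validation set into
groups with median PFS 2.3 vs 36.6 months (log-rank p ≈ 1e-4), and an NNT
of 1.12 means nearly every predicted low-risk patient is a responder. The
same workflow is available from the shell via `mumo simulate / train /
evaluate / ablate`.

`res.ablation()` retrains unimodal and simple-combiner variants
(element-wise product, sum, concatenation, ± reports, ± patient info) on
identical splits and returns the AUC table.

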