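# Methods

`ceusalnm` implements a dual-branch text–video contrastive classifier for
predicting axillary lymph node metastasis (ALNM) from breast
contrast-enhanced ultrasound (CEUS) video, together with the preprocessing,
prompt machinery, adapter fine-tuning, evaluation harness and a synthetic
data generator that make the whole pipeline testable end to end on one CPU.

## Model

**Video branch.** Each sampled frame (grayscale, scaled to [0, 1]) is cut
into non-overlapping `patch_size × patch_size` patches; each patch is
linearly projected to a token of width `d`. Every token receives a learned
spatial position embedding (per patch location, shared across frames) and a
learned temporal position embedding TPE_i (per frame, shared by all of that
frame's tokens). Tokens of all `T` frames are concatenated frame-major and
encoded *jointly* by a pre-LayerNorm transformer, so attention may cross
frames. Each frame is then summarised as the mean of its output tokens
(there is no class token), and the `T` frame vectors are consumed in
temporal order by a single-layer unidirectional LSTM. The final hidden
state is linearly projected to the shared space (dimension `d_s`) and
L2-normalized. An ablation switch replaces the LSTM with mean pooling over
frames, which makes the encoder provably frame-order-invariant when the
TPE table is constant — a test uses this to localise where temporal
information enters.

**Text branch.** Prompts are lowercased and segmented into subword units in
the byte-pair-encoding style (a merge table can be loaded; the built-in
vocabulary uses whole words from the prompt/clinical vocabulary with
character fallback, so nothing is downloaded). Ids carry start/end markers,
are padded to a fixed context length, and truncated end-marker-preserving.
A learned positional table plus a bidirectional transformer encode the
sequence; padding positions are masked out of attention keys, so pads can
never influence the embedding (tested). The sequence is pooled at the end
marker, projected to `d_s` and L2-normalized.

**Similarity and loss.** For a batch of B clips and B texts,
`S[i,j] = τ·⟨v_i, t_j⟩` with a learnable log-temperature (init exp = 14).
Row-softmax of `S` gives the video→text distribution `p_x2y`; row-softmax
of `Sᵀ` gives `p_y2x`. The target for row i is uniform over same-label
columns — with batch size 4 and two classes duplicate labels per batch are
certain, so one-hot targets would be systematically wrong. The loss is

    L = ½ [ mean_i KL(q_x2y_i ‖ p_x2y_i) + mean_j KL(q_y2x_j ‖ p_y2x_j) ]

with an ε = 1e-8 floor inside the logs. Taking the target as the *first*
KL argument keeps the loss finite for (near) one-hot targets; the reverse
direction is infinite for any imperfect p and therefore unusable as a
training objective. This is the one deliberate deviation from the loss as
sometimes written with the arguments in the other order.

**Prompt pool and classification.** Training texts are built by drawing one
template uniformly from a pre/mid/post prompt pool (per instance per step)
and filling the class label into its `{}` slot; when `use_clinical_text` is
on (default), the patient's clinical attribute strings are appended as a
suffix sentence. At inference every template is rendered with each class
label; the class score is the mean cosine similarity between the video
embedding and that class's ensemble (max aggregation available), and
probabilities are the softmax of τ·scores. Because training texts carry the
clinical suffix — a known input at test time, unlike the class label — the
same per-patient suffix is appended to the inference ensembles, keeping
train and test texts in the same distribution. Disabling random prompts
(the "Baseline" ablation) degenerates to the pool's first template, fixed
for every instance.

**AFTO adapters.** A residual bottleneck adapter per branch refines the
shared-space embedding: `F_new = W2 relu(W1 F + b1) + b2`,
`F_mix = α·F_new + (1−α)·F_raw`, re-normalized. The blending ratio α is the
logistic squash of an unconstrained scalar (init 0 → α = 0.5) updated by
backpropagation. The up-projection initializes with sd 1e-3, so the adapter
starts near the identity and fine-tuning begins at the base representation.
Bottleneck defaults to `d_s/4`. With adapters attached and
`freeze_backbone=True` (the default, meant for pretrained backbones) only
the adapters and the temperature train.

## Autodiff engine

No deep-learning framework is used: all neural components run on a small
in-repo reverse-mode autodiff engine over float64 numpy arrays
(`ceusalnm.autodiff`), with layers (linear, embedding, layer norm,
multi-head attention, transformer block, LSTM) and AdamW in `ceusalnm.nn`.
Every gradient path used by the model is verified against central finite
differences in the test suite. Float64 keeps batch-vs-single consistency
checks tight (≤ 1e-5).

## Preprocessing

CEUS exports carry device text and black margins. The keyframe is
binarized at intensity threshold 50 (strict `>`; the boundary convention is
pinned so tests are exact), the largest 8-connected component's tight
bounding rectangle is taken as the imaging region (ties broken by smallest
top-left corner), and that one rectangle — computed from the keyframe only,
to avoid per-frame jitter — crops every frame of the clip before bilinear
resize to the model input size (64×64 at desk scale). Model inputs are 10
frames sampled uniformly (floor of evenly spaced positions) from the
±5-frame window around the reader keyframe; the window *shifts* at clip
boundaries rather than shrinking, and a window shorter than the requested
frame count is an error.

## Synthetic data generator

The generator emulates the statistical structure the classifier relies on,
not ultrasound physics. Each patient contributes one 120-frame 128×128
clip: a noise-free annotation band (intensity 230) across the top 16 rows,
black margins, a central imaging rectangle of speckled tissue (baseline 70,
multiplicative Gaussian speckle σ = 0.12, clipped to [0, 255]), and an
elliptical lesion whose added intensity follows a gamma-variate
wash-in/wash-out curve

    I(t) = peak · τ^a · exp(a (1 − τ)),   τ = (t − onset) / t_p,   t_p = a / rate

with shape a = 2, so the curve rises from onset to a unique maximum `peak`
at `t_p` frames past onset and decays; doubling the rate halves the
time-to-peak. Class-conditional kinetics encode the hypervascularity of
aggressive tumours: metastatic lesions wash in faster (rate 0.16 ± 0.03 vs
0.08 ± 0.015 frames⁻¹) and enhance more strongly (peak 170 vs 120 above
tissue). The keyframe is the frame of maximal mean lesion intensity. Four
clinical attribute categories (basic clinical data, histopathological
biomarkers, CEUS parameters, conventional ultrasound parameters) draw value
strings from small class-conditional tables; real clinical variable
definitions are not public, so these vocabularies are placeholders that
only need to correlate with the class. Everything is reproducible from the
config seed, and a byte-identity test pins it.

What passing tests on this generator do *not* show: robustness to scanner
variability, probe motion, lesions off-centre or partially imaged,
annotation overlays inside the imaging region, or genuinely ambiguous
kinetics — the synthetic classes are separable by design, so end-to-end
results here demonstrate that the pipeline can extract a class-dependent
perfusion signal, not clinical performance.

## Training and evaluation

Folds are assigned at the patient level: per class, shuffled patients are
dealt round-robin into the currently least-loaded fold, which keeps
per-fold class counts within one of the stratified ideal and makes the
folds a partition (both asserted on every run). Training uses AdamW
(decoupled weight decay 0.01) with cosine-decayed learning rate, batch
size 4, horizontal flip + intensity jitter applied uniformly across a clip,
runs at least `min_epochs`, early-stops on validation loss with patience 10
and restores the best-validation weights. Reported scores are the
metastatic-class probabilities of the prompt-ensemble classifier;
metrics are sensitivity, specificity, accuracy, precision, F1 (confusion at
score ≥ 0.5), trapezoidal ROC AUC (ties averaged; constant scores give
0.5), aggregated fold-wise as mean ± sd, and decision-curve net benefit
`NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t)` against treat-all and treat-none.

**Ablation suites.** The module suite runs six configurations (Baseline,
+RP, +AFTO video/text/both, +RP+AFTO) under identical folds and seeds.
Because the mechanism AFTO targets is parameter-efficient adaptation of a
*pretrained* backbone, the driver can first contrastively pretrain the
backbone on a disjoint synthetic source cohort (`pretrain_backbone`); the
Baseline then fine-tunes everything while AFTO rows freeze the backbone and
train only adapters + temperature. Without a pretraining cohort all rows
train from scratch and the adapters act as extra capacity only. The frame
suite sweeps 2, 4, 8, 10, 12, 16 and 32 input frames, widening the keyframe
half-window to ⌈n/2⌉ where the default ±5 window could not supply the
requested count; a clip too short for a configuration records a per-run
error and the suite continues.

## Desk-scale protocol

The study-scale protocol (6-layer encoders, ≥50 epochs) targets GPU
hardware. The presets used by the examples, tests and acceptance script
are the package's CPU-scale counterpart, chosen once: width 32, 2 layers,
2 heads per encoder, 64×64 inputs with patch 16 (16 patches/frame),
context length 32, shared dimension 32; cohorts of 60 patients (30/30);
24 epochs at learning rate 6e-4 with temperature initialized at 4 rather
than the CLIP-style 14 — with a randomly initialized backbone a sharp
similarity softmax stalls the first epochs of contrastive optimization,
and the log-temperature is learnable in any case. One fold trains in
seconds; the full-method 5-fold CV takes under a minute.

## Numerical and design choices

- Strict `>` binarization; 8-connectivity; bbox tie-break smallest (y0, x0).
- Frame sampling: floor of `n_out` evenly spaced positions spanning the
  clamped window inclusive (for the 11-frame window and n_out = 10 this
  drops the 10th window frame); window shifted, never shrunk, at
  boundaries.
- End-marker pooling for text (padding invariance); mean-over-tokens frame
  pooling for video; final LSTM hidden state (not the output sequence).
- Uniform prompt sampling over the pooled template list, one draw per
  instance per step.
- ε = 1e-8 floors in KL logs; softmax max-shift treated as a constant.
- Classification ties go to class 0 (argmax convention).
- Stratification warns (best-effort) rather than failing when a class has
  fewer members than folds.
- The generator's `tissue_intensity` (default 70, above the binarization
  threshold) makes the imaging rectangle a single connected component so
  the crop recovers it exactly; setting it to 0 yields the fully black
  noiseless background variant used in some tests.

## Known limitations

- No pretrained CLIP weights are shipped or downloaded; an import hook
  (`DualBranchModel.import_backbone_weights`) accepts externally converted
  checkpoints with key remapping, but all shipped results start from
  random init or in-repo synthetic pretraining.
- The synthetic task saturates (AUC ≈ 1) at the default separation, so
  metric differences between configurations are small and near the noise
  floor of 12-sample validation folds.
- Single-channel input; colour Doppler overlays and multi-plane studies
  are out of scope, as are lesion segmentation and DICOM parsing.
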