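# Methods

## Pipeline

The package implements a two-stage training scheme for referable
diabetic-retinopathy (DR) classification. Stage one is self-supervised:
an encoder and a 2-layer projection head are trained with the NT-Xent
contrastive loss on pairs of augmented views of unlabeled fundus images,
where with probability 0.70 a view starts from a pre-synthesized
style-transferred variant of the source image rather than the original.
Stage two transfers the encoder weights one-to-one into a classifier
(the projection head is discarded; transfer happens at the pooled
representation h), attaches a fresh two-logit head, and fine-tunes the
whole network with cross-entropy on labeled images (referable = grade ≥ 2).

All tensor computation is in-package numpy: convolution via im2col,
manual backpropagation, LARS and Adam optimizers. This keeps the artifact
dependency-free beyond the scientific Python stack and makes every
training step bit-reproducible under a seed on a single thread.

## Contrastive loss and optimization

For 2N views with embeddings z, each ordered positive pair (i, j)
contributes −log[exp(sim(zᵢ,zⱼ)/τ) / Σ_{k≠i} exp(sim(zᵢ,zₖ)/τ)] with
cosine similarity and temperature τ (default 0.5; the temperature is a
free parameter of the method, exposed in config). Rows are L2-normalized
inside the loss, making it invariant to per-row scaling; the analytic
gradient is implemented alongside and verified against central
differences and a brute-force double-loop oracle.

The projection head input is layer-normalized (parameter-free,
per-sample). Pooled ReLU features are all-positive and share a dominant
mean direction; without this normalization every embedding starts nearly
parallel and the loss sits at its collapse fixed point. Per-sample
normalization avoids the batch-statistics nondeterminism of batch norm.

LARS applies per-layer trust ratios `tc·‖w‖/(‖g‖+wd·‖w‖)` to
multi-dimensional tensors; biases are exempt (standard practice) and take
plain momentum-SGD steps at the base learning rate. Because of that
exemption the desk preset pairs a *small* base learning rate (0.01) with
a *large* trust coefficient (0.1): the product sets weight steps near
0.1% of the layer norm while keeping bias steps small. The large-batch
configuration documented in `PretrainConfig` defaults (batch 2048,
lr 0.3, weight decay 1e-5, 100 epochs) reflects the method's published
operating point and is not intended for single-CPU runs.

Training stops at the epoch budget or when the relative loss improvement
over a sliding window (default 10 epochs) falls below 1e-3. The desk
preset disables the saturation stop: at this scale the loss sits on a
plateau for roughly 25 epochs before view-matching features emerge, and a
plateau detector would end training right there; desk runs therefore use
their full epoch budget.

## Style transfer

AdaIN re-scales each content feature channel to the style channel's
spatial mean and population standard deviation, blended by α (default
1.0); constant content channels receive a variance floor of 1e-5 with a
warning. The feature space comes from a small convolutional autoencoder
trained by reconstruction MSE on a mix of synthetic fundus images and
style textures (held-out MSE must fall below 0.010 per pixel, checked on
a fixed holdout split). The statistic alignment at the AdaIN layer is
exact regardless of decoder quality, and the tests assert it there.
Working sizes are configurable; the desk profile encodes content and
style at 32–64 px (the published configuration used 512/128 with a
pretrained VGG feature space, which is out of desk scope). Stylized
variants are synthesized in advance (default 2 per image, styles drawn
without replacement within an image) and sampled on the fly during
pretraining.

## Synthetic data

`synthgen` renders fundus-like images: circular aperture on black, a
reddish base with tint jitter, a smooth linear illumination gradient, a
branching vessel walk from the optic disc, a bright disc and dark fovea,
and grade-dependent lesions — dark microaneurysm dots, larger dark
hemorrhage blobs, bright exudate patches — with per-grade count ranges
(0,0)/(1,2)/(4,7)/(8,12)/(12,18) for grades 0–4. Lesion radii are chosen
so the smallest lesions remain above the pixel scale at 32 px (radii
≈ size/28, size/10, size/14); at that resolution pathology must survive
crops, flips, ±30° rotations and blur to be learnable at all, which is
the regime the benchmark needs.

The class-independent nuisance is two-component: a smooth random color
field plus a high-frequency oriented grain (per-image orientation,
wavelength 3–6 px, per-channel amplitude). The grain is the deliberate
confounder: it survives geometric and color augmentation (it is a
pattern, not a palette), so a contrastive learner *without* NST can match
views by texture alone, while style transfer replaces exactly these
statistics and forces shape-based matching. The texture RNG stream is
seeded independently of the grade, so texture carries no label
information by construction. Every image ships a sidecar JSON object log
(lesion type, position, radius), letting tests reason about content
without pixel forensics.

What the generator does **not** emulate: camera optics, realistic vessel
topology, inter-patient anatomical variation, label noise, or the true
EyePACS class proportions (a 4.4:1 referable imbalance is kept). Passing
benchmarks on this cohort demonstrates that the pipeline's machinery and
its qualitative contrasts behave as designed, not that the numeric AUCs
transfer to clinical data.

## Quality screening

The five exclusion criteria (uneven illumination, color distortion, low
contrast, motion blur, missing landmarks) are transparent heuristics:
low-pass luminance range, chromaticity distance from a reference fundus
color balance, one minus the luminance IQR, one minus Laplacian variance,
and one minus the peak normalized correlation with a bright-disc
template. Each raw measure is divided by a calibration scale (fixed once
against clean synthetic fixtures) so all scores share a [0,1] range and a
single threshold (default 0.80); an image exceeding several criteria is
excluded once, attributed to its highest-scoring criterion.

## Splits and label fractions

Cross-validation folds are stratified by the referable label
(scikit-learn StratifiedKFold, seeded). Label-fraction subsampling
permutes each class once per seed and takes a prefix of
round(fraction·class size), so smaller fractions are nested inside larger
ones and label-efficiency curves are monotone in data rather than
re-drawn.

## Evaluation

AUC is the Mann–Whitney statistic (ties half-weighted, computed from
midranks); its variance and the paired two-classifier test follow
DeLong's structural-components method with a normal approximation
(two-sided p). The operating threshold maximizes Youden's
J = sensitivity + specificity − 1 over the distinct scores (positive call
at score ≥ threshold), with ties broken toward higher sensitivity and
then lower threshold, and J quantized at 1e-10 so exact ties are not
split by float noise. Sensitivity/specificity confidence intervals at the
operating point use a 2000-replicate stratified bootstrap; the AUC CI can
also be bootstrapped (config), DeLong being the default.

## Desk benchmark

`benchmark.run_desk_benchmark` generates 600 images per seed (32 px,
4.4:1 imbalance), partitions them 390/90/120 into pretraining
pool / validation / held-out test (stratified), trains the coder, caches
2 stylized variants per pool image, pretrains the small encoder for 20
epochs with and without NST (the standalone desk preset defaults to 50;
the benchmark uses the shorter budget that already separates the arms),
and fine-tunes three initializations
(NST-pretrained, plain-pretrained, random) on a 10% label fraction for 8
epochs, scoring held-out AUC. Three seeds take about 4 minutes on one
CPU. The assertions are qualitative and mirror the published contrasts:
pretrained-with-NST beats random initialization at 10% labels, and NST
pretraining is at least as good as pretraining without it.

## Known limitations

The desk-scale contrastive task is hard: with a 3-conv encoder and
32 px views the positive-pair similarity gap grows slowly, and the
NST arm learns shape features only partially within the epoch budget.
The benchmark's contrasts are means over seeds; individual seeds can
order differently. The ResNet50/224 px/batch-2048 configuration of the
published method is represented by configuration defaults and by the
smaller registered encoders (`small`, `wide`, `small_resnet`), not by an
actual ResNet50 implementation.
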