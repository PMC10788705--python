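# Methods

## Backbone model

Each subject is a time series of segmentation label maps (background, blood
pool, myocardium), one map per cardiac frame. A shared per-frame variational
encoder maps each frame to a Gaussian latent code (mean and log-variance of
dimension `d`); a decoder reconstructs the frame from a latent sample; a
two-layer classifier predicts the binary outcome from the `T·d` concatenated
per-frame codes. The training objective is

```
L = L_RE + λ_KL · L_KL + λ_C · L_C (+ λ_N · L_N)
```

where `L_RE` is the reconstruction cross-entropy, `L_KL` the closed-form
Gaussian KL against the unit normal `½ Σ_d (μ² + σ² − 1 − log σ²)` (summed
over latent dimensions, averaged over frames and batch), `L_C` the
classifier cross-entropy, and `L_N` one of the strategy terms.

Architecture choices (none of which the strategies depend on):

* **Block-pooled MLP instead of a convolutional stack.** The one-hot label
  maps are average-pooled over 4×4 blocks before the encoder (64×64 → 16×16
  cells carrying per-class area fractions), and encoder/decoder are
  single-hidden-layer MLPs. Label maps carry no texture, so the pooled area
  fractions preserve the geometry that matters (radii, thickness,
  contraction), and pooling keeps the whole benchmark tractable on one CPU
  core. Random flips and right-angle rotations commute with block pooling,
  so augmentation on the pooled grid is exact. The decoder reconstructs at
  the pooled resolution (per-cell class distributions); `decode(...,
  upsample=True)` returns input-resolution maps by nearest-neighbour
  upsampling.
* **The classifier consumes latent means during training and evaluation;
  latent *samples* feed only the decoder and the uncertainty machinery.**
  Feeding sampled codes to the classifier acts as a strong noise
  regulariser which pins the classifier near perfect calibration regardless
  of the training objective — a regime in which uncertainty-aware training
  has nothing to correct and which large image classifiers do not inhabit.
  With the deterministic classifier path, the backbone shows the familiar
  mild overconfidence that the strategies target.
* **Latent dimension d = 64 by default.** The latent width is the
  classifier's effective capacity (its input is `T·d`). With small `d` the
  classifier cannot interpolate its training set and converges to the
  Bayes posterior — again leaving no calibration pathology to study. `d=64`
  (512 classifier inputs for 8 frames against ~430 training subjects)
  reproduces the overfitting-driven overconfidence regime of deep
  classifiers at desk scale. All widths are constructor arguments.
* **Optimisation.** Adam, batch size 8, learning rate 1e-3 for the VAE and
  3e-3 for the classifier (both configurable; a single shared rate is one
  assignment away). Training runs a fixed number of epochs; per-epoch
  validation BACC and ECE are recorded together with a parameter snapshot,
  so model selection is a pure post-hoc function of the record stream.
* **Reproducibility.** Every stochastic component (initialisation,
  shuffling, augmentation, latent draws, confidence sampling) draws from a
  seed derived from `random_state` plus a stable component label
  (`component_seed`), so identical seeds give identical record streams.

## Strategy terms

* **Paired Confidence Loss** (margin `μ`, default preset 0.6): for each
  predicted class, all (incorrectly predicted, correctly predicted) pairs
  contribute `max(0, P_incorrect − P_correct + μ)`, normalised by the pair
  count per class so batch size does not rescale the loss. The per-pair
  normalisation is our choice; the defining properties (zero at margin,
  positive when an incorrect prediction outranks a correct one) do not
  constrain it.
* **Probability Loss**: mean wrong-class probability per ground-truth
  class, `(1/|G|)Σ_G P(negative) + (1/|Ḡ|)Σ_Ḡ P(positive)`. A class absent
  from a (size-8) batch contributes nothing rather than dividing by zero.
* **Confidence Weight** (floor `w`): `C_i` is the positive fraction of K=20
  classifier passes, the first over the latent means and the remaining 19
  over reparameterised draws, recomputed every batch outside the gradient
  path (the weights multiply the loss; they are not a differentiable
  function of the parameters). `W_i = g_i(1−C_i) + (1−g_i)C_i`,
  `W_S,i = (1−w)W_i + w`. The published optima are w=1 (CRT) and w=2
  (CAD); both are outside the floor semantics of the scaling formula (w=1
  fixes every weight at 1, w>1 inverts the weighting) and are kept exactly
  as published, with a warning. Note that floors well below 1 systematically
  *down-weight confidently correct samples*, which drives the classifier
  toward underconfidence: the weighted-cross-entropy stationary point in a
  region with error rate q has confidence `w(1−q)/(w(1−q)+q)`, not `1−q`.
  The strategy therefore helps when the baseline is overconfident and hurts
  when it is already calibrated.
* **AvUC** (threshold warm-up): predictions fall in four cells by
  correctness and by predictive entropy vs. a threshold; the loss is
  `log(1 + bad/good)` with the soft cell masses `r(1−tanh u)`, `r·tanh u`,
  `(1−r)(1−tanh u)`, `(1−r)tanh u`. The threshold is fixed at 1 for the
  first 3 epochs (binary entropy never exceeds ln 2 ≈ 0.693, so everything
  starts "certain") and is then set each epoch to the mean entropy of the
  correctly classified training samples. An all-bad batch has an empty
  denominator; it is floored at ε = 1e-8 and logged. A hard-count mode
  serves as the non-differentiable reference. Because binary predictive
  entropy is bounded by ln 2, `tanh u` cannot saturate to 1; soft and hard
  modes therefore agree tightly only where the bad-cell mass vanishes.
* **Soft ECE** (M bins, temperature T, order p): sample i belongs to bin j
  with weight `softmax_j(−(r_i − c_j)²/T)` over equispaced bin centers
  `c_j`; membership-weighted bin mass, accuracy and confidence enter
  `(Σ_j (|B_j|/n)|A_j − R_j|^p)^{1/p}`. Defaults M=15, T=0.1 (0.01 in the
  CAD preset), p=1 — with p=1 and T→0 the loss recovers the hard ECE
  whenever no confidence lies exactly on a bin edge. Empty soft bins are
  guarded with an additive 1e-30 on the mass before the ratio.
* **MMCE** (kernel width 0.4): with the Laplacian kernel
  `k(r_i, r_j) = exp(−|r_i−r_j|/width)`, the loss is the squared RKHS
  distance between the mean embedding of incorrect-sample confidences
  (weights `r_i`, normalised by the incorrect count) and of correct-sample
  miscalibration mass (weights `1−r_i`, normalised by the batch size):
  incorrect-pair term + correct-pair term − 2·cross term. Written this way
  the loss is non-negative up to round-off. The width 0.4 follows the
  construction this loss originates from and is exposed as a
  hyperparameter.

Published per-strategy hyperparameter optima are shipped as presets
(`LossHyperparams.preset(strategy, task)`, tasks `"crt"`, `"cad"`); the
`"desk"` preset used by the synthetic benchmark reuses the CRT values.

## Synthetic benchmark

Each subject is a contracting ring (myocardium) around a disk (blood pool):
outer radius `r(t) = r0 · (1 − a·s(t))` with a smooth cosine contraction
curve `s(t)` over the cycle, ring thickness 0.3·r (minimum 2 px so the ring
stays closed), plus per-subject center and radius jitter. The contraction
amplitude is `a = base + effect·y + N(0, noise_sd)`:

* `effect_size` (default 0.10) vs `noise_sd` (default 0.06) sets the class
  overlap — with these defaults the Bayes-achievable balanced accuracy is
  ≈ 0.8 before label noise, matching the difficulty regime of real
  treatment-response and diagnosis cohorts (reported accuracies ~0.7)
  rather than a toy separable task;
* `label_flip_rate` injects aleatoric difficulty by flipping outcome labels
  (the benchmark uses 0.15, capping test BACC near 0.72);
* `n_subjects`, and the train fraction, set epistemic difficulty.

The generator emulates the *geometry and difficulty* of segmentation-based
outcome prediction, not its appearance: there is no segmentation-model
error structure (inputs are clean phantoms), no multi-slice anatomy, no
scanner variation, and the outcome depends on a single latent factor
(contraction amplitude). Passing tests therefore demonstrate that the
machinery behaves as specified under controlled difficulty — not that any
strategy will improve calibration on a particular clinical dataset.

Splits are label-stratified by the largest-remainder rule (per class), so
splits are disjoint and exhaustive and per-split prevalence is within one
subject of the global prevalence. The benchmark split is 0.72/0.08/0.20.

## Uncertainty estimation

* **Epistemic**: K=20 classifier passes per subject — the first over the
  latent means, the rest over reparameterised draws. Raising K only
  refines the sampled confidence within its binomial standard error.
* **Aleatoric**: K−1 perturbed copies of the input stack, where labels of
  pixels in the 1-pixel 4-neighbour boundary band are resampled (to a
  uniformly chosen neighbour's label) with probability 0.2, emulating the
  boundary variability a stochastic segmentation model produces at the
  same nominal rate. The exact dropout-induced error distribution of a
  real segmentation network is not reproduced.
* `C = (# positive predictions)/K`; the metric suite under uncertainty
  uses confidence `max(C, 1−C)` and the majority-vote prediction (exact
  ties predict positive; implemented by an infinitesimal nudge that
  perturbs no metric by more than 1e-12). Using the original (first-pass)
  prediction for accuracy instead of the majority vote is exposed as an
  option.

## Experiment protocol

Per seed: the VAE is pre-trained alone (6 epochs), then every strategy
trains VAE + classifier for 30 epochs from that shared state; the final
model is the checkpoint with the highest validation BACC (ties to the
earliest epoch); an alternative selection by lowest validation ECE is
recomputed from the same record stream without retraining. Test-split
metrics are aggregated over seeds as mean ± sd (median for the headline
baseline-vs-Confidence-Weight comparison), with McNemar's test against the
baseline (exact binomial below 25 discordant pairs, chi-square with
continuity correction above). Grid search evaluates an exhaustive
hyperparameter grid on the validation split, selecting by validation BACC
with ties broken toward the lexicographically smallest parameter tuple so
the result is independent of enumeration order. The desk problem sizes
(600 subjects, 8 frames, 64×64, 30 epochs, 3–5 seeds) are chosen so the
complete comparison runs in minutes on a single CPU core.

## Numerical conventions

* Equal-width confidence bins are half-open `[lo, hi)` with the last bin
  closed: confidence c lands in bin ⌈c·M⌉ and c=0 in bin 1. Adaptive bins
  are contiguous in stable confidence-rank order with sizes differing by at
  most one; the remainder goes to the lowest-rank bins.
* Empty bins contribute zero to ECE/OE and are excluded from MCE.
* Prediction ties (p = 0.5) resolve to class 0; majority-vote ties in
  sampled predictions resolve to positive.
* The Brier score is the squared distance between the 2-vector of class
  probabilities and the one-hot outcome (range [0, 2]); the positive-class
  scalar variant (half the value) is available via `variant="positive"`.
* Losses are computed in float64; analytic gradients of every
  differentiable term match central finite differences to a relative error
  below 1e-4 (verified in the test suite). Non-smooth points (hinge kinks,
  argmax ties, bin edges) use standard subgradient conventions.
* A training step aborts with the offending term named if any loss term
  becomes non-finite.

## Known limitations

* Binary classification only; no multiclass calibration.
* No post-hoc recalibration (e.g. temperature scaling) — training-time
  methods only.
* The AvUC soft/hard agreement is structural only where the numerator mass
  vanishes, because binary entropy caps `tanh u` at ≈ 0.6.
* The synthetic benchmark's single latent factor makes feature learning
  easy; conclusions about strategy rankings transfer to real cohorts only
  directionally.
* The backbone is desk-scale by design: no convolutional encoder, one
  slice, no GPU path.
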