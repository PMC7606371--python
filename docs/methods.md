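# Methods

This note documents the model, the training procedure, the synthetic data
generator, and the numerical choices behind `dmriqa`, in the package's own
terms. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

Diffusion MRI acquires many 3D volumes per subject; motion artifacts
(ghosting, signal dropout, blurring) degrade individual slices, hence
volumes, hence subjects. Quality is rated on a three-level ordinal scale —
pass < questionable < fail — at three hierarchy levels. The operating
assumptions:

* no pristine reference image exists (no-reference IQA);
* expert annotation exists only at volume (or subject) level and in small
  quantity; slice labels are **inherited** from the volume annotation, so a
  mixed-quality volume mislabels some of its slices;
* a fraction of annotations may simply be wrong (rater error).

## Networks

Both networks are built from four block types (NHWC layout throughout):

* **DSConv unit**: 3×3 depthwise convolution → 1×1 pointwise convolution →
  batch norm → ReLU. Parameter count 9c_in + c_in·c_out, versus 9·c_in·c_out
  for a full 3×3 convolution.
* **DSR block**: two DSConv units followed by 2×2 max-pooling; shortcut
  branch is a 1×1 convolution with stride 2; outputs are summed. Spatial
  dims halve (inputs must be even).
* **Nonlocal block**: embedded-Gaussian attention
  r_i = Σ_j softmax_j(φ(x_i)ᵀψ(x_j)) · g(x_j) with φ, ψ, g learned 1×1
  convolutions; the attention matrix is row-stochastic by construction.
* **NLDR block**: DSR with a nonlocal residual insert (x + nonlocal(x))
  placed immediately before pooling.
* **NLR block**: identity-shortcut nonlocal residual; shape preserved.
* **CLF head**: 3×3 convolution to 3 channels → global average pooling →
  softmax.

**SQA-Net** (slice rater): DSR(c₁) → DSR(c₂) → NLDR(c₃) → NLDR(c₄) →
NLR(c₄) → CLF. Full-scale widths are 32/64/128/256 on 144×144 inputs
(feature tap 9×9×256 at the NLR output); the desk-scale spec quarters the
widths on 64×64 inputs. **VQA-Net** (volume rater) consumes the frozen NLR
feature maps of a volume's slices: shared 1×1 reduction (256→16 full scale),
channel concatenation in slice order (the volume rater is deliberately not
permutation invariant), NLR, CLF.

Design points that were genuinely open and how they were fixed:

* each DSR/NLDR main path has exactly two DSConv units;
* no activation after the residual sum (post-activation ordering);
* convolutions followed by batch norm carry no bias;
* argmax ties in a probability triple break toward the more severe label
  (conservative for quality control);
* the nonlocal value kernel g is zero-initialized so every nonlocal block
  starts as an identity inside its residual and the attention pathway is
  learned gradually; φ and ψ start small (σ = 1/√c) so early attention is
  near uniform.

## Loss

Class-balanced focal loss with L2 regularization:

    L(p_t) = −α_t (1−p_t)^κ log p_t + (λ / 2 n_w) Σ_w ‖W_w‖²

with α_t = max(N₁,N₂,N₃)/N_t computed from the per-class sample counts of
the stage's own training space (slices for the slice network, volumes for
the volume network), λ = 0.01 over the n_w convolution weight matrices
(batch-norm scale/shift and biases excluded), and focusing exponent κ ≥ 0.
p_t = 0 is clamped to 1e-7 rather than raised. The full-scale default is
κ = 2; the desk-scale recipe uses κ = 1 because hard-example mining
re-amplifies unfittable mislabeled samples under heavy label noise (see
*Desk-scale training recipe*). During retraining rounds after label
cleansing a class may be legitimately absent; its (unused) balance weight is
then computed as if one sample were present instead of aborting — the
strict all-classes check applies to initial pre-training only.

## Training procedure

1. **Pre-training**: supervised fit of SQA-Net on the (weakly) labeled
   slices.
2. **Semi-supervised learning** (default 2 rounds): predict all unlabeled
   slices; slices whose maximal probability strictly exceeds TH-S = 0.9
   join the pool as pseudo-labels; retrain. Pseudo-labels are refreshed
   every round.
3. **Slice self-training** (default 2 rounds): predict every trainable
   slice; keep it if the prediction agrees with its current label OR clears
   TH-S; relabel kept-and-confident disagreements; remove the rest; retrain.
   Removed slices stay removed. The same TH-S serves stages 2 and 3.
4. **Volume label initialization**: unlabeled volumes get a rating by the
   slice-count rule (pass if >60% of slices pass; fail if fail slices
   outnumber each of the other classes — the "each" reading; a "sum"
   reading is available via `fail_rule="sum"`; questionable otherwise)
   applied to predicted slice labels.
5. **VQA-Net training** on frozen slice features.
6. **Volume self-training** (default 2 rounds) with TH-V = 0.9.

Label provenance (given / inherited / pseudo / relabeled / removed) is
tracked on every record and the full pipeline emits an audit of all label
changes. "Previous iteration" at the first self-training round means the
record's current stored label — the only defined predecessor.

## Optimizer

RMSprop (ρ = 0.9, ε = 1e-7) with the 1/(1 + decay·t) schedule; full-scale
defaults lr = 1e-5, decay = 5e-8. Two deliberate departures from a textbook
setup, both with a mechanism:

* **Decoupled weight decay.** Feeding the L2 gradient through RMSprop's
  per-coordinate normalization turns the penalty into a constant lr-sized
  shrinkage of every small-gradient weight (for g → λW, the update tends to
  lr·sign(W)), which steadily erases a trained model at desk-scale learning
  rates. The decay term is therefore applied directly as p ← p − lr·(λ/n_w)p
  outside the adaptive scaling.
* **Optimizer-state continuity.** Every retraining stage continues with the
  same optimizer instance: restarting the second-moment estimates on a
  trained model produces large uniform first steps that measurably destroy
  the fit.

## Desk-scale training recipe (`TrainConfig.toy`)

The full-scale recipe (lr 1e-5 over ~7×10⁵ slices on GPU) does not transfer
to a few hundred CPU-sized samples, so the desk-scale configuration used by
the tests and the acceptance script sets: lr 1e-3, decay 2e-2, 16
pre-training epochs, 2 epochs per retraining round, 30 epochs for the cheap
volume-network fits, batch 32, κ = 1, no augmentation, refinement step scale
0.1, and Polyak averaging ema_rho = 0.95. Rationale for the non-obvious
entries:

* *16 pre-training epochs*: the refinement thresholds (0.9) presuppose a
  base model in the high-training-accuracy regime; an undertrained model
  selects almost no pseudo-labels and self-training amplifies its errors.
* *Polyak (EMA) stage-end weights*: under ~25% effective label noise the
  class-rebalanced loss induces an epoch-scale limit cycle in the weights
  (the predicted class distribution swings between modes); the EMA of the
  trajectory is representative where a single snapshot is a lottery. This
  is the standard remedy in semi-supervised ("mean teacher") training.
* *No augmentation*: rotation/flip augmentation fights overfitting, but the
  desk-scale regime underfits — augmentation only adds gradient variance.
  At full scale augmentation stays on (rotation 0–30°, horizontal flip,
  training time only).
* *κ = 1*: the focusing exponent is exposed in config; its full-scale value
  is not pinned by any external constraint we can verify, and κ = 2 at toy
  scale provably destabilizes training under label noise.

Batch norm uses batch statistics in training and debiased exponential
running averages (zero-initialized, corrected by 1−m^t, m = 0.9) at
inference; without the debias correction a briefly-trained model's
inference statistics are dominated by their initialization.

## Synthetic data generator

`synthetic_data` emulates the study conditions at desk scale:

* **Phantom**: deterministic per-seed brain-like ellipse with smoothed
  internal blobs and a cortical-rim band, intensities in [0,1], zero
  background.
* **Artifacts**, all monotone in a severity s ∈ [0,1]: half-FOV ghost
  replica (weight 0.5s), up to 3 zeroed horizontal dropout bands, Gaussian
  blur (σ = 1.5s px), Rician-style noise (σ = 0.01 + 0.08s; the 0.01 floor
  is always present).
* **Labels**: severity < s₁ → pass, < s₂ → questionable, else fail;
  thresholds default (0.3, 0.6).
* **Volumes** draw an intended class (probabilities 0.57/0.16/0.27,
  mirroring the imbalance of a clinical pool) and slice severities from a
  per-class Beta mixture — pass (1.2, 8), questionable (5, 5), fail
  (8, 2.5). The volume's true label is recomputed from its slices by the
  initialization rule, so mixed volumes genuinely mix.
* **Annotation regime**: weak labeling copies each volume's stored label to
  all its slices (provenance `inherited`); `flip_rate` reassigns exactly
  round(flip_rate·n_volumes) volume labels to a uniformly chosen different
  class. Default fixture scale is 4 subjects × 12 volumes × 16 slices of
  64×64; the full-scale geometry (151 volumes × 60 slices of 144×144) is a
  configuration away.

What the generator does **not** emulate: real diffusion contrast and its
b-value dependence, eddy-current or susceptibility artifacts, anatomical
variation across age, scanner- and protocol-specific noise structure, and
rater disagreement patterns. Passing the behavioral tests therefore shows
the training machinery recovers labels under controlled weak/noisy
annotation — not that the trained toy model transfers to clinical data.

## Label-recovery experiment

`experiments.label_recovery_experiment` runs the full pipeline at desk
scale (2 labeled + 2 unlabeled + 1 test subjects, 12 volumes × 16 slices
each, 20% volume-label flips) and measures held-out accuracy after each
stage. Volume-level accuracy at the intermediate slice stages is obtained
by rule-aggregating predicted slice labels (the volume network does not
exist until stage 4); the final stages use VQA-Net proper. The acceptance
suite asserts that the refined model beats the pre-training-only baseline
on held-out slices in ≥ 4 of 5 seeded replicates and that no refinement
stage degrades held-out volume accuracy by more than one standard error.

## Numerical choices and degenerate inputs

* float32 working precision in the network engine; the loss module computes
  in float64. Gradients of every layer are finite-difference-checked in
  float64 in the test suite.
* Preprocessing: zero-pad to the square target (remainders to bottom/right),
  then min-max normalize over the padded array; a constant slice maps to
  all zeros. Inputs larger than the canvas raise — cropping is refused.
* Max-pool gradient routes to the first argmax on ties.
* Strict inequalities throughout the rules and thresholds; boundary cases
  fall to the middle class.
* Confusion-matrix metrics: one-vs-rest SEN/SPE per class; a class with no
  actual (or no negative) examples yields NaN, not an exception. The single
  reported accuracy is trace/total.

## Known limitations

* The NumPy engine is CPU-bound; full-scale training (144×144, widths to
  256, ~10⁶ slices) is out of its intended range — the full-scale NetSpec
  exists for architecture fidelity, not full-scale training runs.
* Parameter counts of the full-scale networks are reported for information
  (`Layer.n_params`) but are under-determined by the published description
  (e.g. internal channel widths of φ, ψ, g), so no exact-count claim is
  made.
* Self-training can still over-cleanse minority classes at very small
  sample sizes; the empty-class tolerance in retraining avoids the abort
  but cannot restore lost classes.
* The subject stage is a fixed rule; no uncertainty is propagated across
  hierarchy levels.
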