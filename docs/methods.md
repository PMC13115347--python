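# Methods

`dynfuse` re-implements, as a tested pipeline on synthetic data, an
interaction-driven dynamic fusion analysis for multimodal depression
screening: a session-level classifier over utterance-level features in
four modality blocks, a controlled 512-condition grid crossing fusion
strategies with affective-pretraining states, and the nonparametric
statistics used to read the grid.

## Task and model

Each subject contributes one interview session: `T` utterances, each
represented by four feature vectors — a visual-semantic embedding
(SigLIP-like, default 768-d), head-pose angles (pitch/yaw/roll, 3-d),
acoustic functionals (eGeMAPS-like, 88-d) and a sentence embedding
(E5-like, 1024-d). The label is a binarized PHQ-9 depression tendency,
y ∈ {0, 1}, with a ~1:4.7 class imbalance (13 of 74 in the emulated
study population).

The network:

1. **Projection.** Each block is projected into a shared d=256 latent
   space. Visual blocks (semantic and pose) are layer-normalized before
   projection. Recipes: semantic `Linear(d_s→256)+ReLU+Dropout`; pose
   mirrors it (`Linear(3→256)`, unspecified in the source design);
   audio `[Linear(88→128)→BatchNorm→ReLU→Dropout] →
   [Linear(128→256)→BatchNorm→ReLU→Dropout]` (the second block widens to
   the shared space, which takes precedence over the printed 128); text
   `[Linear(1024→256)→LayerNorm→GELU→Dropout] × 2`.
2. **Staged fusion.** Three positions, left to right: semantic+pose
   (`vis_fusion`), +audio (`audio_fusion`), +text (`text_fusion`). At
   each position one of four operators acts on the running stream h_a
   and the incoming stream h_b, both (T × d):
   * concatenation: `Linear([h_a; h_b]) → h` (2d² weights);
   * summation: `h_a + h_b` (0 parameters);
   * gating: `g = σ(W_g[h_a; h_b] + b_g)`, `h = g⊙h_a + (1−g)⊙h_b`
     (2d²+d parameters). The gate is an elementwise vector of width d,
     following the elementwise product in the defining equations; a
     scalar-gate variant is a config switch. `g` is the interpretability
     trace;
   * cross-attention: single head, d_k = d, identity query (Q = h_a),
     `K = W_K h_b`, `V = W_V h_b`, `α = softmax(QKᵀ/√d_k)`, context
     `c = αV`, output `W_O[h_a; c]` (exactly 4d² weights). With one
     head and d_k = d a learned query projection is redundant up to the
     reparametrization `W_QᵀW_K → W`, so dropping it changes capacity
     essentially not at all while matching the stated ~4d² overhead —
     twice concatenation's. `α` (rows sum to 1) is the trace.
3. **Temporal attention pooling** (MIL-style): `α_t ∝ exp(wᵀh_t)`,
   session vector `h = Σ α_t h_t`.
4. **Classifier:** `ŷ = σ(W_o h + b_o)`.

Gated and attention operators are defined generically for any
(primary, complementary) pair so each can occupy any position; the
primary stream is always the running fused representation. Disabled
modalities (`use_audio`/`use_text` = False) turn their stage into an
identity with no parameters instantiated.

## Training

Weighted binary cross-entropy with the per-fold positive-class weight
w_pos = n_neg/n_pos computed from the training-fold labels; no
resampling. AdamW (lr 1e-3, weight decay 1e-4), gradient clipping at
global norm 1.0, early stopping on validation AUC (defaults: 100
epochs, patience 10, batches of 8 sessions; validation is one fold
rotated out of the training folds). A focal-loss variant (α=0.25,
γ=2.0, combined with w_pos; with α=1, γ=0 it reduces exactly to the
weighted BCE) is available by config but excluded from the default
grid. Probabilities are clamped at ε=1e-7 inside the losses.

Affective pretraining trains a modality's projection plus a throwaway
softmax affect head on that modality's pretraining corpus; only the
projection weights (including normalization statistics) are saved and
used to initialize the downstream model. All parameters remain
trainable downstream.

There is no GPU framework in the runtime environment, so the package
carries a small reverse-mode autodiff and layer library on numpy
(`dynfuse.tensor`, `dynfuse.nn`); every operation and layer is
gradient-checked numerically in the test suite. The models involved are
small enough (≤ ~1M parameters, sessions of ≤ 40 utterances) that this
is not a practical constraint.

## The grid and its statistics

The full grid crosses 4³ = 64 strategy triples with 2³ = 8 binary
pretraining states (visual/audio/text) — 512 conditions, identical
hyperparameters throughout, each evaluated with subject-independent
k-fold CV (no subject in more than one fold; every fold holds ≥1
positive and ≥1 negative subject; singleton folds are rejected).

Analysis, on condition-level means (folds averaged first):

* **Fusion-position tables** (AUC and PR-AUC): Kruskal–Wallis across
  the four strategies within each position, tie-corrected, with effect
  size η² = H/(N−1) using the *per-cell* N (128 under the full grid).
  This per-cell convention is deliberately how the emulated analysis
  applied the formula — all its printed effect sizes equal H/127 — and
  the conventional pooled-N formula is available via `use_total_n`.
* **Pretraining table**: per modality, pretrained vs scratch condition
  groups compared by two-sided Mann–Whitney U; Δ = mean(PT) − mean(SC);
  effect labelled Positive/Negative/n.s. at α = 0.05. An "all three
  pretrained vs all scratch" row is included.
* **Gate table**: per gated-vis condition, the subject-level mean gate
  g is reduced to Δ_s = g_s − (1 − g_s) and tested by paired t across
  subjects. Dominance classes: strong (Δ>0.5, p<0.05), moderate
  (0<Δ≤0.5, p<0.05), balanced (p≥0.05), reversal (Δ<0, p<0.05). A
  zero-variance nonzero Δ (saturated gate) is reported with t = ±∞ and
  a p floor of 0.
* All tests are two-sided at α=0.05, mid-rank ties, raw p-values (no
  multiple-testing correction), matching the emulated reporting.

PR-AUC uses the average-precision (step-function) definition; its
random baseline equals the positive prevalence (0.176 at 13/74).
ROC-AUC uses the rank (Mann–Whitney) formula with mid-rank ties.

## Synthetic world

A linear-Gaussian latent-factor generator: per subject a scalar affect
score z_i = y_i + subject_sd·b_i, per utterance z_it = z_i +
utterance_sd·e_it, and each modality row is `effect_m · z_it · L_m +
noise_sd · ε` with a fixed unit loading L_m per modality. One shared
factor makes the modalities complementary views, so gating and
attention have something real to redistribute. Defaults emulate the
study population: 74 subjects, 13 positive, 20–40 utterances per
session, visual-semantic effect 1.0 dominant over pose 0.15 (so the
gate analysis has a planted direction), audio/text 0.5.

Pretraining corpora carry a balanced 4-class affect label graded along
an affect axis, centered on the target corpus grand mean. The
domain-shift knob δ does three things at once: an additive mean shift
(δ·u_m), covariance inflation (noise × (1 + 0.25δ)), and a rotation of
the affect axis away from the target loading (fully orthogonal at
δ ≥ 2). The rotation is essential: a mean shift and scale change alone
leave the class-discriminative direction intact, and pretraining on
such a corpus still transfers positively — "domain mismatch" that can
produce *negative* transfer must change which feature directions carry
affect, which is the stated interpretation (recording conditions as the
critical domain boundary). Defaults: visual δ=0 (matched), audio δ=2.5
(shifted), text δ=1.0 (partial) — the positive/negative/null transfer
pattern of the emulated study.

What the generator does **not** emulate: frame-level dynamics below the
utterance level, temporal autocorrelation within sessions, nonlinear
modality interactions, label noise, and the covariance structure of
real SigLIP/E5/eGeMAPS features. A green test therefore establishes
that the pipeline detects the planted structure under the stated model,
not that the architecture ranks the same way on real clinical data.

## Desk-scale profile and the recovery experiments

The full-scale defaults (768/1024-d features, d=256, 512 conditions)
are runnable but slow on one CPU. `desk_scale_config()` is the
documented CI-speed profile: n=200 subjects (35 positive, the same
~1:4.7 imbalance), dims {16, 3, 8, 12}, d=16, 10–20 utterances, k=3
folds, 30 epochs with patience 6. The widths and noise (0.6) were set
so a scratch-trained model reaches test AUC ≈ 0.72–0.85 — headroom
comparable to the emulated study's 0.73–0.77 — after observing that a
first candidate (48-d visual, noise 1.0, 6 epochs) produced a world
where the network memorized per-utterance noise at chance-level
validation AUC while a regularized linear baseline reached 0.84.

The parameter-recovery experiments (`dynfuse.experiments`) mirror the
transfer and gate findings directionally:

* **Transfer arms** fine-tune on a deliberately short budget (8 epochs,
  batches of 8): initialization effects are only visible while training
  cannot wash out the starting point — with the full 30-epoch budget
  measured transfer deltas shrink to noise. The visual arm compares
  pretrained vs scratch across all four vis-fusion strategies (36 runs
  per group), the way the grid-level transfer table pools matched
  conditions; a single-condition comparison is underpowered for any
  honest effect. The audio arm uses summation at the audio stage — the
  configuration in which an incoming stream cannot be down-weighted,
  and the one where the emulated analysis itself reports pretraining
  sensitivity to be strongest — with a large shift (δ=5).
* **Gate arm**: gated-vis models at the full desk budget; per-subject
  gate means pooled over test folds (each subject counted once per
  seed), then the paired gate analysis.

## Numerical choices and known limitations

* Probabilities clamped at 1e-7 in losses; softmax computed shifted;
  sigmoid computed in the numerically stable split form.
* Attention at T=1 yields α = [1.0] exactly; pooling of identical rows
  returns that row for any scorer.
* The pre-projection LayerNorm discards per-utterance magnitude. When
  the planted signal is far larger than the feature noise this is
  lossy (rows collapse toward ±L̂ and class-0 subjects split by the
  sign of their random effect); at realistic signal-to-noise it is a
  benign rescaling. Toy configurations in the tests avoid the extreme
  regime.
* BatchNorm inside the audio projection normalizes over the utterances
  that share a forward pass; during per-session training this removes
  part of the session-mean (subject-level) audio signal. This follows
  the stated recipe and is compensated by the other streams.
* Fold assignment is round-robin after stratified shuffling, so fold
  sizes differ by at most one and every fold gets ⌊n_pos/k⌋ or
  ⌈n_pos/k⌉ positives.
* All randomness flows from a single integer seed through named
  `SeedSequence` child streams (loadings / target / pretrain / folds /
  model init / batch order), so every dataset, fold, initialization and
  batch order is reproducible bit-for-bit.
* SDs printed in the emulated study's tables describe dispersion of a
  private corpus and are not reproduced; statistical comparisons here
  are about signs, orderings and the printed arithmetic, not levels.
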