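# Methods

This note documents the models, procedures and numerical choices behind
`mieeg`, in the order data flows through the package.

## Synthetic ERD/ERS EEG

The generator emulates the statistical structure a sensorimotor-rhythm
decoder exploits, not the biophysics of any particular recording system.
Per trial and channel it sums:

* **background**: 1/f^α noise (default α = 1), synthesized in the frequency
  domain and scaled to 10 µV RMS — the broadband floor of scalp EEG;
* **rhythms**: white noise band-passed into 8–12 Hz (μ) and 13–30 Hz (β)
  with total RMS `snr × 10 µV`, split 2:1 in energy between μ and β
  (μ-dominant idling). Band-limited noise rather than sinusoids is used so
  that class information lives in bandpower, as in real EEG, and cannot be
  read off trivially from phase;
* **ERD**: in the channel assigned to the trial's class (round-robin
  lateralization; for 3 channels / 2 classes: class 0 → C3, class 1 → C4)
  the rhythm envelope is multiplied by `1 − erd_depth` for t ≥ 0. The
  pre-cue 0.5 s stays at baseline, matching cue-locked desynchronization;
* **subject gain**: one log-normal multiplicative factor per subject
  (σ = `subject_gain_sd`, default 0.2), giving strictly positive
  inter-subject amplitude variability;
* **EOG**: one ocular channel of steep (1/f²) low-frequency noise at 3 µV
  RMS; a fraction of trials receives a half-sine deflection of 0.5 s whose
  peak reaches `artifact_amplitude` (default 150 µV), signed to agree with
  the underlying trace so the peak magnitude is guaranteed.

Defaults (9 subjects, 3 channels, 250 Hz, epochs −0.5…4 s, balanced classes,
`erd_depth 0.5`, `snr 2`, 10 % artifact trials) describe a moderately
separable binary paradigm on a bipolar montage. Equal specs (including the
seed) produce bit-identical datasets.

**What the generator does not emulate** — volume conduction and realistic
channel covariance, non-stationary drifts, session effects, EMG, and
subject-specific spectral peaks. Passing tests on this corpus therefore
demonstrate that the pipeline's machinery is correct and that the decoders
can exploit bandpower contrasts; they say nothing about accuracy levels on
real recordings.

## Preprocessing

Fixed order: common-average reference → cue-locked epoching (half-open
sample windows, `round(x·fs)` arithmetic; 1125 samples for −0.5…4 s at
250 Hz) → EOG rejection → band-pass → splitting → standardization.

* **EOG rejection** uses a strict inequality (peak > 100 µV rejects; a trial
  at exactly the threshold is kept) and runs before filtering so screening
  sees raw amplitudes. Datasets without an EOG block pass through with a
  warning.
* **Band-pass**: 8–30 Hz, 4th-order Butterworth, applied forward-backward
  (zero net phase, squared magnitude response). Edge handling uses
  Gustafsson's initial-condition method, chosen because it makes the
  operation exactly symmetric under time reversal (≈1e-10 relative); mirror
  padding was measured to leave ~0.17 edge asymmetry on 1000-sample epochs,
  which would break the zero-phase reversal identity the test suite
  enforces.
* **Standardization** is per channel, pooling trials × samples within a
  subject, with parameters fitted on the training portion only. The
  `sd_floor` of 1e-6 maps constant channels to exact zeros.
* **Splits** are per-subject and stratified. Counts use round-half-to-even
  (`n_test = round(f_test · n)`, then `n_val = round(f_val · (n − n_test))`)
  and classes are apportioned by largest remainder, keeping per-class counts
  within one of exact proportionality; remainder ties break toward the lower
  class index. Two named schemes exist: 20 % test / 25 %-of-remainder
  validation, and 15 % / 18 %. Splitting is deterministic per (seed,
  subject).

## The decoder family

One declarative `ModelConfig` builds every variant. Input is
`(B, 1, n_samples, n_channels)`; output is class logits.

* **Deep branch**: two blocks of [2-D conv → batch-norm → activation →
  temporal max-pool (stride 2) → dropout 0.4]. The first kernel spans all
  channels jointly with its temporal extent (7 samples); this design choice
  collapses the spatial axis in the first block so that both branches emit
  `(B, F, T′, 1)` with a shared `T′ = n_samples / 4`.
* **Shallow branch**: spatial conv over all channels (80 filters) →
  temporal conv (25 samples) → batch-norm → activation → average-pool
  (stride 4) → dropout 0.4.
* **Fusion**: concatenation (64 + 80 = 144 features) followed by a pointwise
  projection to 128 with bias.
* **Context**: fixed sinusoidal positional encoding (parameter-free), then a
  post-norm transformer encoder — default 8 layers, d = 128, 4 heads, GELU,
  feed-forward width 256 (2×d; the architecture description leaves this
  width open). No dropout inside the encoder; regularization lives in the
  named conv/BiLSTM/MLP dropouts.
* **Sequence model**: 3 bidirectional LSTM layers, 128 hidden per direction,
  dropout 0.3 between layers; outputs are mean-pooled over time.
* **Head**: 128-unit hidden layer with the variant's activation, dropout
  0.5, linear output.
* **Variants**: `scratch_simplified` reduces to 6 transformer / 2 BiLSTM
  layers with positional encoding off. `tl_relu` / `tl_tanh` swap the
  activation and scale fusion, feed-forward and BiLSTM widths via
  `width_multiplier` (2.08 / 1.80), calibrated so the totals land near
  9.49 M and 7.17 M parameters; these multipliers are this package's own
  estimates of unexplained enlarged variants, not measured facts. `tl_lstm`
  adds a parallel unidirectional LSTM on the fused sequence, concatenated
  before pooling — one reasonable interpretation of an "additional LSTM
  branch".

With the defaults the full variant has ≈2.34 M trainable parameters (3-ch
binary geometry). Published counts near 1.35 M for this depth/width
combination are not reachable: the BiLSTM stack alone holds ≈1.05 M and the
transformer ≥0.53 M; parameter accounting in this package is therefore
verified against independent shape arithmetic, not against external totals.

Initialization is fan-in uniform, drawn from a seeded generator; identical
(config, seed) pairs produce identical parameters. All computation runs on
the package's float64 NumPy autograd engine (`mieeg.nn`) — a deliberate
CPU-scale design that keeps the dependency surface small and every run
bit-reproducible; the cost is that full-size, full-schedule training is out
of desk reach, so experiments default to reduced widths.

## Training regimes and freezing

Adam with fixed learning rate, cross-entropy loss, batch 64:

| regime            | epochs | learning rate |
|-------------------|--------|---------------|
| scratch           | 150    | 1e-3          |
| finetune_full     | 150    | 5e-4          |
| finetune_reduced  | 75     | 5e-5          |

Fine-tuning applies a freeze policy before the first step: convolutional,
recurrent and head layers stay trainable; by default the lower half of the
transformer encoder is frozen (layers 0–3 of 8), on the rationale that lower
layers hold the most general temporal representations. Frozen tensors are
excluded from the optimizer and remain bit-identical. Model selection keeps
the epoch with the best validation accuracy (ties → earliest); without a
validation set the final epoch is kept. No LR scheduling, weight decay or
augmentation.

Cross-geometry transfer (different channel or class counts) rebuilds and
re-initializes only the channel-spanning convolutions and, if needed, the
output layer, copying all temporal, transformer and recurrent weights. This
adapter is an interpretation; nothing forces it to be the only way to move
a 3-channel model to 22 channels.

## Evaluation

Two protocols coexist deliberately:

* **strict LOSO** — the held-out subject appears in no training or
  validation batch (asserted at runtime); validation is a stratified 20 %
  carve-out of the training subjects' trials. Used for models without
  per-subject adaptation (baselines, pooled training).
* **per-subject transfer** — each subject's own trials are split by the
  named scheme; the model is pretrained on the pooled other subjects,
  fine-tuned on the subject's training split and scored on its test split.
  This is how "subject-specific scratch vs transfer" comparisons are run.

Standardization inside both protocols is fitted on the respective training
portion only (pooled training subjects in LOSO; the subject's training split
in the transfer protocol), so mutating test data cannot change fitted
parameters.

Metrics come from confusion matrices, making accuracy (trace/total, %),
macro-F1 (unweighted mean of per-class F1, 0 for a class with no predictions
and no instances) and Cohen's κ ((p_o − p_e)/(1 − p_e)) mutually coherent by
construction. Aggregates: η = A/P reported to 3 decimals, Δσ to 1 decimal,
accuracy to 2; improvement deltas are returned unrounded. Paired two-tailed
t-tests across subject accuracies are uncorrected for multiple comparisons;
the comparison count is the caller's to log. Degenerate cases: identical
vectors → (t=0, p=1); zero-variance nonzero-mean differences → p=0 with a
warning; Δσ is undefined (None) when the baseline spread is zero, which
happens at tiny problem sizes.

## Baselines

* **CSP**: per-trial covariances are trace-normalized before class
  averaging (standard stabilization); filters solve the generalized
  eigenproblem of (C₀, C₀+C₁), so whitened eigenvalue pairs sum to one and
  the filters diagonalize both class covariances. `n_components = 4`
  (2 per spectral extreme); features are log-variances of the projections;
  rank-deficient composites get a logged ridge. Binary only — multiclass
  CSP strategies are out of scope.
* **LDA** uses least-squares solving with shrinkage 1e-6 (a ridge on the
  pooled covariance).
* **RandomForest**: one subject-specific forest (200 trees, depth 20) on
  flattened trials, with a configurable feature-matrix size guard.

## Experiments and problem sizes

The workbench's five templates compare: (A) subject-specific scratch vs
pretrain+full-fine-tune; (B) full vs reduced fine-tuning; (C) ELU vs ReLU vs
Tanh on the same architecture and plan (width multiplier 1 — the activation
effect is isolated from the unexplained size enlargement); (D) transfer
across corpora with different geometry via the spatial adapter; (E) shallow
baselines. Runs default to desk scale: reduced widths
(8/16 conv filters, fusion 32, BiLSTM 16), short epochs via
`epochs_override`, and small synthetic corpora (typically 3–4 subjects,
8–15 trials per class, 1.5–2 s epochs). These sizes were chosen so a full
experiment completes in tens of seconds on one CPU core while still
exercising every code path; the canonical regime hyperparameters are
recorded unchanged in every manifest. Reports contain no timestamps, and a
self-consistency audit recomputes every aggregate from the emitted
per-subject confusion matrices.

## Known limitations

* The autograd engine is single-threaded float64 NumPy; it is built for
  correctness and reproducibility, not throughput. Full 1125-sample,
  full-width training runs are possible but slow.
* The synthetic corpus is intentionally idealized; accuracy levels reached
  on it (often 100 % for shallow probes) do not transfer to real EEG.
* Multiclass CSP, ocular correction (ICA/regression), notch filtering and
  resampling are explicitly not implemented.
* The GDF reader is optional and untested against real competition files in
  this repository; it exists as an ingestion adapter for users who hold the
  recordings.
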