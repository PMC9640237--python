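# Methods

This note documents the models, the numerical choices, and the open design
decisions behind `kymovoice`, in the order data flows through the package.

## Synthetic data model

**Glottal waveform.** The observable is the glottal half-width per frame.
Cycle `c` spans `[τ_c, τ_c + T_c)` and contributes a rectified cosine
`A_c · max(0, cos(2π(t − τ_c)/T_c))` — a standard first-order description
of glottal opening: the gap opens for half the cycle and stays closed for
the other half. The cosine phase puts each cycle's peak exactly at its
start, so peak-to-peak intervals equal the drawn periods; this makes the
injected perturbations recoverable without smoothing bias. Each open lobe
carries a single amplitude, with amplitude switches placed mid-cycle
(during closure) so shimmer does not introduce discontinuities.

**Perturbations.** Jitter and shimmer are i.i.d. Gaussian multiplicative
perturbations of per-cycle period and amplitude with coefficient of
variation `percent/100`, matching the conventional perturbation-percent
definitions. Note the identity relating the two common summary statistics:
for i.i.d. perturbations with CV `j`, the *local* jitter
(mean absolute successive period difference over mean period) has
expectation `(2/√π)·j ≈ 1.128·j`. Tests and recovery checks account for
this factor.

**Noise and HNR.** White Gaussian noise is added to the harmonic signal
*before* rectification, with power `var(clean)/10^(HNR/10)`; the generator
returns the clean and noise components separately so the realized SNR can
be verified (it lands within ~0.1 dB of the request for recordings of
≥100 cycles). HNR = ∞ is the noiseless case.

**Rendering.** Frames show the glottis as a dark vertical slit of per-frame
half-width `round(w_t)` columns, centered horizontally, with vertical
extent around `glottal_row`, on brighter reddish tissue. The tissue texture
is a deliberately *aperiodic* seeded random field (smoothed Gaussian noise
plus a gentle vertical gradient): a periodic shading pattern can alias with
the dark slit during registration and corrupt drift recovery. Camera drift
is a slow vertical sinusoid rounded to integer pixels — integer so that
rigid integer-shift registration has an exactly recoverable ground truth.
The blue channel receives strong extra Gaussian noise (default SD 25),
emulating the noisy blue channel of color high-speed sensors; 8-bit
quantization and clipping happen after noise.

**Parameter table.** `generate_dataset` draws true parameters uniformly
from per-class ranges, simulates ~60 cycles per phonation, and *measures*
f0, jitter, and shimmer back from the waveform with the package's own peak
analysis; HNR is measured from the realized clean/noise variances (capped
at 60 dB for noiseless draws). The tabulated features therefore carry
realistic measurement scatter — peak quantization to the frame grid
inflates measured jitter by roughly 1–3 percentage points at typical
period lengths, for both classes. Default class ranges (healthy: jitter
0.2–1%, shimmer 1–3%, HNR 20–30 dB; disordered: jitter 2–8%, shimmer
6–14%, HNR 5–15 dB) are typical sustained-phonation values.

**What the simulator does not emulate.** Photorealistic tissue appearance,
specular reflections, mucosal-wave asymmetry between the two folds,
horizontal drift, deformable motion, illumination changes, and audio.
Passing tests on this generator demonstrates that the pipeline recovers
*its* ground truth — cycle perturbations, drift, vocalized intervals —
not that it handles every artifact of clinical recordings.

## Preprocessing

**Temporal segmentation.** Per-frame motion energy is the mean absolute
green-channel difference between consecutive frames. A frame is vocalized
when its energy exceeds the configurable quantile (default 0.5) of the
energy distribution; sub-threshold gaps of ≤5 frames are closed (the
closed phase of a cycle produces no inter-frame change), and runs shorter
than 20 frames are dropped. The detector is invariant to global intensity
offsets by construction. Segmentation precedes motion compensation;
compensation is then applied within each segment.

**Motion compensation.** Drift is modeled as a rigid integer vertical
translation. Consecutive frames are registered pairwise by maximizing
normalized cross-correlation over shifts in ±16 px, and pairwise shifts are
accumulated outward from the reference frame. Two choices matter and were
forced by measured failures of the naive alternative: (1) *pairwise*
rather than direct-to-reference matching — neighbouring frames show nearly
the same glottal configuration, so the dark gap is an alignment feature,
whereas a wide-open reference matched against a closed-glottis frame
misregisters because the gap block dominates the window statistics; and
(2) matching on the *vertical derivative* of the green channel, which
removes the mean-offset bias a large uniform dark region induces in the
correlation. Correlation is evaluated only on genuinely overlapping rows;
ties resolve to the smallest |shift|, making compensation idempotent.
Constant (degenerate) frames keep their neighbour's displacement, with a
warning.

**Kymogram extraction.** Column `t` of the kymogram is row `row` of frame
`t`; rows of the kymogram index position along the cross-section. Output
is `(space, time, 3)` uint8.

## Features

Red and green intensities are used directly; the blue channel is never
read. The gradient feature is computed on the mean of red and green
(neither remaining channel is privileged) as central differences at a
configurable pixel distance (default 8) along both axes with edge
replication; both the signed components and the magnitude are exposed, and
the feature matrix uses the magnitude. Pooling is per-pixel or per-time-
column (row means).

## Peak search

A window of length `L` slides one sample at a time. Left and right
sections take `L//3` samples each; the center keeps the remainder. The
window-center sample is a peak iff the center-section statistic (default
max; min/median/mean available) strictly exceeds the left section, is ≥
the right section, and the center sample is the leftmost maximum of the
window. The asymmetric ≥/`>` pair implements the deterministic tie rule
"leftmost sample of a plateau". With `L = 3` and the max statistic the
rule reduces exactly to a strict-local-maximum test, which is the oracle
used in tests. Peaks closer than `L//2` samples to either end of the
signal cannot be window centers and are not reported.

## DBN classifier

**Energy and conditionals.** The bottom RBM is Gaussian–Bernoulli with
per-visible-unit noise SD σ_j and visible offsets C_j; conditionals are
`p(h_i=1|v) = logistic(c_i + Σ_j (v_j/σ_j) W_ji)` and
`v_j|h ~ N(C_j + σ_j Σ_i W_ji h_i, σ_j)`. Upper layers are
Bernoulli–Bernoulli and consume the activation probabilities of the layer
below. Tests verify the conditionals against Bayes on the enumerated
joint `exp(−E)` to 1e−6.

**σ is fixed, matched to the data scale.** Features are min–max scaled to
[0, 1] on the training split only. After that scaling the per-feature SD
is ≈0.25–0.47; a unit σ would make the model's noise several times the
signal, which measurably stalls both CD pretraining (weights barely grow,
upper layers see near-constant input) and the subsequent fine-tuning. The
pipeline therefore fixes σ_j to the per-feature SD of the scaled training
data (floored at 0.05 for near-constant features). σ is never learned.

**Contrastive divergence.** CD-k (default k=1): the data-side term uses
exact `p(h|v)`; the chain samples hidden states binarily and, for Gaussian
layers, uses mean-field visible reconstructions (binary samples for
Bernoulli layers, so the long-chain limit is a proper Gibbs sampler —
verified against the exact enumerated gradient of a tiny RBM, direction
cosine > 0.99). Increments for weights and both bias vectors carry
momentum. Reconstruction error is logged per epoch against the mean-field
reconstruction.

**Pretraining vs fine-tuning rates.** CD always runs at a conservative
fixed rate (0.05, momentum 0.5, epochs capped at 15): aggressive CD
settings inflate the hidden biases and strand the supervised phase in a
poor basin. The tuned learning rate and momentum govern fine-tuning only.

**Fine-tuning.** A softmax head is attached and the mean cross-entropy is
backpropagated through the deterministic sigmoid activations of every
layer (analytic gradients match central finite differences to 1e−5
relative at step 1e−4). Optimization is minibatch momentum SGD. The epoch
loss is monitored and the learning rate halves only on genuine divergence
(loss > 1.25× previous). A strictly-monotone-loss rule was tried and
rejected: a small-init sigmoid network starts at a nearly exact symmetric
saddle (loss ≈ ln 2), and the only way past it is a momentum-driven
transient that temporarily raises the loss; enforcing monotonicity pins
training at the saddle indefinitely.

**Prediction.** Softmax probabilities; label = argmax. An optional
Hamming-distance tie-breaker (nearest per-class binary prototype of the
top hidden layer) exists for exact probability ties but is off by default.

**Defaults.** Architecture [n_features, 32, 16]; weight init N(0, 0.01²),
zero biases; fine-tuning lr 0.1, momentum 0.9, 30 epochs, batch 32. All of
these are exposed to the tuner.

## Farmland fertility optimizer

Population N=40 in k=4 equal index-blocks ("soil regions"); memory
fractions t=0.5 give local memories of round(t·N/k)=5 and a global memory
of round(t·N)=20 best individuals (numpy round-half-to-even; both sizes
must be ≥1). Per iteration: the worst region (largest mean fitness) moves
by `x + h₁(x − x_mem)` with `h₁ = α·U(−1,1)` and `x_mem` drawn per
individual from the global memory; all other individuals move by
`x + h₂(x − x_peer)` with `h₂ = β·U(0,1)` and peers drawn from a pre-phase
population snapshot; memories are refreshed; each individual is fused with
the best solutions — with probability Q (default 0.7) by
`ω₁·(x − best_global)`, otherwise coordinate-wise by
`U(−1,1)·(x_j − best_local_j)`; and ω₁ decays by a fresh U(0,1) factor
(initial value 1, so E[ω₁] halves per iteration).

Two decisions were genuinely open and are resolved as follows:

* **Replacement is greedy in every phase** (a proposal replaces its
  individual only when fitness strictly improves). This makes the
  best-so-far trace provably monotone and is necessary for convergence:
  with unconditional replacement the expansion-type moves `x + c(x − y)`,
  `c ≥ 0`, inflate the population toward the box bounds and the optimizer
  stalls at fitness ~10³ on the 10-D sphere benchmark.
* **The fusion local branch is sign-symmetric and per-coordinate.** The
  directional variants were both measured to fail: moving only *away*
  from the local best never improves a convex objective (the phase
  contributes exactly zero accepted moves), while moving only *toward* it
  collapses population diversity and freezes the search, since every move
  in the algorithm scales with inter-individual distances. The symmetric
  per-coordinate form subsumes both directions, preserves diversity, and
  drives the 10-D sphere to ~1e−8 median (20 seeds, 500 iterations) and
  2-D Rosenbrock to ~1e−8 within the same budget.

Out-of-bounds proposals are clipped. All randomness flows from one seeded
generator with a documented draw order, so single iterations can be
replayed against hand-traced formulas in tests. The best-ever solution is
tracked across all evaluations and returned with a per-iteration
best-so-far trace.

## Pipeline and evaluation

Splits are stratified 60/20/20 (train/validation/test), seeded. The tuner
minimizes `1 − validation accuracy` over a 6-dimensional unit box encoding
learning rate (log scale, 1e−3–0.3), momentum (0–0.95), epochs (5–40), two
hidden sizes (8–64, 4–32), and CD steps (1–3); integer parameters round on
decode, so every decoded point is a valid configuration. Each objective
evaluation trains a DBN with a fixed seed, making the objective a pure
function of the encoded vector (evaluations are cached). The encoded
default configuration is injected as a warm start into the initial
population, so by elitism the tuned result is never worse than the default
on the validation split. The default tuning budget (population 8, 6
iterations, ~60 trainings) keeps a full run on 400 phonations under a
minute on one CPU; the acceptance script uses the same sizes.

The evaluation report treats *disordered* as the positive class:
sensitivity = recall = TP/(TP+FN), specificity = TN/(TN+FP), precision =
TP/(TP+FP), F = harmonic mean of precision and recall. The AP rate is the
recall in percent and the EP rate its complement (AP + EP = 100 by
construction). MSE is the mean squared error between the predicted
positive-class probability and the 0/1 label, reported in percent. Zero
denominators yield 0 by convention. Percentages print to two decimals.

## Known limitations

* The simulator's slit geometry and rigid vertical drift are idealized;
  registration accuracy on deformable clinical motion is untested.
* Measured jitter/shimmer inherit a `2/√π` factor and frame-grid
  quantization bias relative to the injected CVs; both classes are
  affected equally, so classification is unaffected, but absolute values
  should not be read as clinical perturbation measurements.
* The DBN is a small dense network for tabular/pooled features, not a
  spatial segmentation model; per-pixel glottis segmentation is out of
  scope.
* FFA constants follow the published recommendations (k=4, t=0.5, Q=0.7,
  ω₁=1); k=3 is supported but not extensively benchmarked.
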