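# Methods

## Problem and model

`seizegraph` classifies fixed-length multi-channel scalp-EEG clips as ictal
(containing at least one second of seizure activity) or interictal.  Each
clip is represented as a tensor **X** ∈ R^{N×C×T}: N = 22 bipolar channels
of the standard temporal-central-parasagittal montage, C = 100 log-FFT
amplitude features per channel per second, and T one-second time steps
(12 or 60).  Electrodes form the nodes of a graph; the network learns which
node-to-node and step-to-step interactions matter for the current input
rather than committing to a fixed adjacency.

A spatiotemporal block applies, in order:

1. **Temporal attention.**  A bilinear score of the layer input produces a
   T×T matrix, passed through a sigmoid, mixed by a learnable T×T matrix,
   and row-softmaxed to E′.  The (N·C)×T unfolding of the input is
   multiplied by E′ on the right, reweighting time steps.
2. **Spatial attention.**  The analogous N×N construction produces a
   row-stochastic S′.  S′ is deliberately left asymmetric, dense, and
   unthresholded: channel-to-channel influence in EEG is directed and even
   weak couplings may be informative.
3. **Attention-modulated Chebyshev graph convolution.**  With L_sym =
   I − D^{−1/2} A D^{−1/2} and L̃ = (2/λ_max) L_sym − I, the filter is
   y_t = Σ_{k<K} (T_k(L̃) ⊙ S′) x_t θ_k followed by ReLU.  K terms reach
   neighbours up to K−1 hops away; the Hadamard product with S′ makes edge
   influence input-dependent while the Laplacian stays fixed (keeping the
   Chebyshev spectral argument intact).  With S′ = 1 the static filter is
   recovered exactly.
4. **Dilated temporal convolution.**  A kernel-size-3, dilation-2
   convolution along the time axis (shared across nodes), symmetric zero
   padding so T is preserved, ReLU.  Reach grows by ±2 steps per stacked
   layer at constant parameter count.

Blocks preserve the (N, ·, T) layout and stack freely (default 2).  The
head flattens the final tensor, applies a ReLU-activated fully connected
layer, then a linear unit and a sigmoid.  The ReLU layer alone cannot emit
a probability, so the linear+sigmoid completion is the minimal closing
choice for a binary classifier.

### Deliberately open details, and what was chosen

* **Base adjacency A.**  Nothing pins down the electrode graph; three
  constructions are provided (`fully_connected`, `distance_gaussian` on
  approximate 10-20 scalp positions, `correlation` = mean absolute Pearson
  correlation of channel feature series over the training split).
  `correlation` is the default: it is data-driven like the attention
  mechanism itself, yet fixed before training so L̃ is static.
* **Association order of the bilinear attention products.**  The score
  expressions are under-parenthesized in their usual statement; the
  standard reading is used (time-collapsed or node-collapsed projections on
  the left, their transposed counterparts on the right; exact contractions
  are documented as einsum subscripts in `attention.py`).  The tested
  contract — shape, row-stochasticity, permutation equivariance — holds
  under any consistent reading.
* **Softmax axis.**  Row-wise (over the second index), matching the printed
  normalization denominators; rows of E′ and S′ sum to 1.
* **Normalization granularity.**  z-scoring is per-(channel, feature)
  element over training clips and time steps; a global-scalar variant would
  also be defensible but discards per-electrode gain differences.
* **Per-block attention parameters** (not shared across blocks): each block
  sees a different feature dimensionality, so sharing is not even
  well-typed for block 1 vs block 2.
* **λ_max** is computed by exact symmetric eigensolve (N ≤ a few dozen);
  the common λ_max ≈ 2 shortcut is available behind a flag.
* **Initialization.**  Fan-based uniform (Glorot-style) for dense/conv
  kernels; attention mixing matrices V_e, V_s start near the identity and
  bilinear projections at small variance so the sigmoid pathway is not
  saturated at step 0.  All draws come from one seeded generator, and every
  parameter group is drawn regardless of ablation switches so ablated and
  full models share surviving initial weights under the same seed.

## Preprocessing

Signals are resampled to 200 Hz (Fourier-domain resampling via
`scipy.signal.resample`), cut into non-overlapping 1-s windows, and each
window maps to log(|FFT| + ε) of the non-negative bins with ε = 1e-8
guarding silent windows.  A 200-sample real FFT has 101 non-negative bins;
the DC bin is dropped (montage-dependent offset, uninformative) and bins
1..100 kept, giving C = 100.  Clip labels follow the ≥ 1 s rule with
overlap *summed* across intervals (contiguity is not required); intervals
are half-open [start, stop) seconds relative to clip start.  Normalization
statistics are computed from the training split only — the fitting
interface takes nothing else, which makes leakage a type error rather than
a discipline.

## Training recipe

Adam at initial learning rate 1e-4, batch size 20, cosine annealing over
the full run (no warm restarts), early stopping after 5 consecutive
validation epochs without loss improvement, binary cross-entropy on the
sigmoid output (computed from logits for stability).  Class imbalance is
addressed exclusively by two label-preserving augmentations:

* **Amplitude scaling** by u ~ Uniform(0.8, 1.2) per clip.  Because
  features are log-amplitudes, scaling the raw signal by u equals adding
  log u to every unnormalized feature bin, so the augmentation runs in
  feature space without re-running FFTs; the identity is exact away from
  the ε floor and verified in the tests.  Both the raw-signal and
  feature-space paths are implemented.
* **Midline reflection** with probability 0.5: channel rows are permuted by
  the left↔right homolog pairing of the bipolar montage.  The pairing is
  derived by mirroring each electrode label across the midline (odd↔even
  digit, Z fixed), yielding 11 swap pairs and no fixed points for the
  22-channel montage, with a validated override hook for custom layouts.

"Iterations" in the stopping rule are read as epochs, since validation
loss is an epoch-level quantity.

## Numerical engine

The network runs on a compact reverse-mode automatic-differentiation tape
over numpy arrays (`seizegraph.autodiff`): broadcasting arithmetic,
two-operand einsum, relu/sigmoid/softplus/softmax, shape ops, slicing and
padding, plus an Adam implementation.  Every primitive's gradient is
checked against central finite differences in the test suite, and the
dilated convolution and graph filter are composites of those primitives.
Float64 throughout; softmax is max-subtracted; BCE uses log1p-style
softplus.  Single-threaded numpy makes fixed-seed runs bit-reproducible.

## Synthetic data: what it emulates and what it does not

The generator plants a controllable spatial-spectral signature:
interictal background is 1/f^a noise (a = 1 by default) plus white sensor
noise; ictal clips add, on a fixed channel subset, an amplitude-modulated
3 Hz spike-wave-like rhythm with two decaying harmonics, 0.5 s on/off
ramps, onsets jittered up to 0.5 s across channels to emulate spread, and
duration 2–10 s so the ≥ 1 s labeling rule always fires.  Ictal/interictal
assignment is i.i.d. Bernoulli; the default prevalence of 5% mirrors the
seizure-time fraction of large clinical corpora.

This emulates exactly the features the model exploits — band-limited
rhythmicity, spatial coherence over a subset of electrodes, temporal
spread — and none of the things that make clinical EEG hard: artifacts
(blink, EMG, electrode pops), patient heterogeneity, non-stationary
background, seizure-morphology diversity.  Passing the learning tests
therefore demonstrates that the implementation can recover planted
structure end to end, not that it attains any particular clinical
performance.

## Problem sizes for the bundled experiments

* **Learning recovery**: 1000 clips, T = 12, prevalence 0.2, the standard
  recipe, at most 10 epochs; the held-out AUC is expected ≥ 0.90 (with the
  default seeds the run reaches ≈ 1.0).  Prevalence 0.2 rather than 0.05
  keeps the positive counts of the three splits statistically meaningful
  at this clip count.
* **Ablation direction**: five seeds × five variants (full and the four
  single-module removals) on 400-clip datasets with a thinner model
  (16 graph / 16 temporal channels, one block) and learning rate 1e-3 with
  up to 20 epochs, so that every variant trains to convergence within the
  study's compute envelope.  The comparison is the median held-out AUC of
  the full model against each ablation.  At this scale the planted task is
  easy enough that converged variants cluster near AUC 1.0; the study
  checks the *direction* (the full model is not beaten), not effect sizes
  — margins between variants are not resolvable on a task this small, and
  the removals that matter most on clinical data (graph and dilated
  stages) are partially compensated here by the fully connected head.

## Known limitations

* The engine is CPU-bound and sized for desk-scale experiments; corpus-
  scale training (hours of EEG, 60-s clips at full width) wants a GPU
  framework.
* The EDF writer emits the minimal subset of the format (uniform rate,
  1-s records, 16-bit) and is intended for round-tripping generated data,
  not for clinical archiving.
* Event-based clinical scoring (onset latency, false alarms per hour) is
  out of scope; metrics are clip-level accuracy, sensitivity, specificity,
  and rank-statistic AUC.  The decision threshold for the confusion-based
  metrics is 0.5 by default, with the Youden-optimal threshold reported
  alongside, since short training runs leave probabilities compressed
  around the base rate.
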