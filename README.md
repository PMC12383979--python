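# seizegraph

Dynamic graph convolutional seizure detection for multi-channel scalp EEG.

Automated seizure detection treats each EEG clip as a classification
problem: does this segment contain ictal activity?  Convolutional and
recurrent models impose a Euclidean layout on what is really an irregular
electrode graph, and classical graph networks freeze the adjacency before
training.  `seizegraph` implements a detector that learns the coupling
structure per input: temporal and spatial attention produce row-stochastic
maps E′ (T×T) and S′ (N×N) from the current layer input, S′ modulates a
Chebyshev spectral graph convolution element-wise, and a dilated temporal
convolution widens the receptive field without adding parameters.  The
package bundles the full pipeline — preprocessing, a seeded synthetic EEG
generator with planted ictal structure, the training recipe, and
evaluation — so everything is testable end to end without access to a
clinical corpus.

## Model

Each clip becomes a tensor **X** ∈ R^{N×C×T} (N = 22 bipolar channels,
C = 100 log-FFT amplitudes per 1-s window, T ∈ {12, 60} steps).  With
L_sym = I − D^{−1/2}AD^{−1/2}, L̃ = (2/λ_max)L_sym − I, and Chebyshev
polynomials T_k(x) = 2xT_{k−1}(x) − T_{k−2}(x), one spatiotemporal block
computes

    X̂        = unfold(X) · E′                      (temporal attention)
    y_t      = ReLU( Σ_{k<K} (T_k(L̃) ⊙ S′) x̂_t θ_k )   (modulated graph conv)
    X_next   = ReLU( Φ *_dilated y )               (dilated temporal conv)

where ⊙ is the Hadamard product and K = 3 reaches two-hop neighbours.
Blocks preserve the (N, ·, T) layout and stack; a fully connected head
(ReLU layer, then linear + sigmoid) emits a seizure probability per clip.
Training follows Adam at lr 1e-4, batch 20, cosine annealing, early
stopping (patience 5), and two EEG-specific augmentations: amplitude
scaling in [0.8, 1.2] and random reflection across the scalp midline.
Metrics are accuracy, sensitivity, specificity and rank-statistic AUC.

See `docs/methods.md` for assumptions, parameter defaults, and the design
decisions taken where the architecture leaves details open.

## Worked example

```python
import numpy as np
import seizegraph as sg
from seizegraph.experiment import run_synthetic_experiment
from seizegraph.training import TrainConfig

spec = sg.SyntheticSpec(n_clips=1000, seizure_prevalence=0.2, seed=11)
result = run_synthetic_experiment(
    spec,
    sg.ModelConfig(seed=11),                      # 22x100x12, K=3, 2 blocks
    TrainConfig(lr=1e-4, batch_size=20, max_epochs=10, patience=5, seed=11),
    split_seed=11)
r = result["report"]
print(f"held-out AUC {r.auc:.3f} on {len(result['splits'][2])} test clips")
```

prints

```
held-out AUC 0.999 on 200 test clips
```

1000 synthetic 12-s clips are generated (20% carry a planted 3 Hz
spike-wave-like rhythm on a subset of channels over 1/f background),
featurized to 22×100×12 log-FFT tensors, split 60/20/20, and the detector
is trained with the standard recipe; the reported AUC is the probability
that a random ictal test clip outscores a random interictal one — 0.999
means the planted structure is recovered almost perfectly within 10
epochs.

The same pipeline is scriptable from the shell:

```bash
seizegraph simulate   --seed 7 --out run/            # clip store (+ EDF export)
seizegraph preprocess --clips run/clips.h5 --out run/
seizegraph train      --features run/features.h5 --out run/ --seed 7
seizegraph evaluate   --checkpoint run/checkpoint.npz \
                      --features run/features.h5 --out run/
seizegraph ablate     --features run/features.h5 --out run/ --seed 7
```

`ablate` trains the full model plus the four single-module removals
(temporal attention, spatial attention, graph convolution, dilated
convolution) and writes one report row each.

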