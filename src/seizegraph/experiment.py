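"""End-to-end synthetic experiment orchestration.

Glue shared by the command-line interface and the reproduction script:
generate labeled clips, featurize, split, build the electrode graph from
the training split, train with the standard recipe, and evaluate on the
held-out split.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import MetricReport, evaluate
from .graph import build_adjacency, normalized_scaled_laplacian
from .model import ModelConfig, SeizureGraphModel
from .montage import reflection_permutation
from .preprocess import featurize_clip
from .synthetic import SyntheticSpec, generate_clips
from .training import TrainConfig, train

__all__ = ["featurize_clips", "three_way_split", "run_synthetic_experiment"]


def featurize_clips(clips, n_features: int = 100):
    """Stack clips into (B, N, C, T) unnormalized features and labels."""
    from .preprocess import EEGClip
    tensors, labels = [], []
    for c in clips:
        clip = EEGClip(samples=c.samples, sample_rate=c.sample_rate,
                       channel_names=c.channel_names,
                       seizure_intervals=list(c.seizure_intervals))
        ft = featurize_clip(clip, n_features=n_features)
        tensors.append(ft.X)
        labels.append(ft.label)
    return np.stack(tensors), np.asarray(labels, dtype=int)


def three_way_split(n: int, seed: int, frac_train: float = 0.6,
                    frac_val: float = 0.2):
    """Shuffled disjoint train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(frac_train * n))
    n_val = int(round(frac_val * n))
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


def run_synthetic_experiment(spec: SyntheticSpec,
                             model_config: ModelConfig,
                             train_config: TrainConfig,
                             split_seed: int | None = None,
                             ) -> dict:
    """Generate -> featurize -> split -> train -> evaluate.

    Returns a dict with the held-out :class:`MetricReport`, the training
    history, the fitted model and the splits (for further analysis).
    """
    clips = generate_clips(spec)
    X, y = featurize_clips(clips, n_features=model_config.n_features)
    tr, va, te = three_way_split(len(y), split_seed if split_seed is not None
                                 else spec.seed)
    A = build_adjacency(model_config.adjacency_mode,
                        n_channels=model_config.n_channels,
                        channel_names=list(spec.channel_names),
                        features=X[tr])
    graph = normalized_scaled_laplacian(A)
    model = SeizureGraphModel(model_config, graph)
    perm = reflection_permutation(spec.channel_names)
    model, history, stats = train(model, X[tr], y[tr], X[va], y[va],
                                  train_config, reflection_perm=perm)
    X_test = (X[te] - stats.mean[None]) / stats.sd[None]
    probs = np.concatenate([model.forward(X_test[i:i + 50])
                            for i in range(0, len(te), 50)]) \
        if len(te) else np.empty(0)
    report: MetricReport | None = evaluate(y[te], probs) if len(te) else None
    return {"report": report, "history": history, "model": model,
            "stats": stats, "graph": graph, "splits": (tr, va, te),
            "X": X, "y": y, "test_probs": probs}
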