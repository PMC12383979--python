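"""Spatiotemporal seizure-detection network.

Each spatiotemporal block runs, in order: temporal attention (reweights the
input along time), spatial attention (produces a row-stochastic channel map
S'), attention-modulated Chebyshev graph convolution (ReLU), and a dilated
temporal convolution (ReLU).  Every stage preserves the (N, ., T) layout, so
blocks stack freely; a fully connected head (flatten -> ReLU layer -> linear
-> sigmoid) turns the final tensor into one seizure probability per clip.

Ablation switches mirror the four removals studied with this architecture:
``use_tatt`` off passes X through unweighted; ``use_satt`` off fixes S' to
the all-ones matrix (the modulated filter degrades to the static Chebyshev
filter); ``use_gcn`` off replaces the graph stage with a per-node linear
channel map (no spatial mixing); ``use_dcn`` off replaces the temporal stage
with a width-1 convolution (no temporal mixing).

The final ReLU-activated fully connected layer cannot itself emit a
probability, so the head appends a linear unit and a sigmoid — the minimal
completion for a binary classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, einsum
from .attention import (SpatialAttentionParams, TemporalAttentionParams,
                        spatial_attention, temporal_attention)
from .graph import GraphStructure, cheb_graph_conv, chebyshev_basis
from .temporal import DilatedConvParams, dilated_conv

CHECKPOINT_FORMAT_VERSION = 1

_ABLATABLE = {"TAtt": "use_tatt", "SAtt": "use_satt",
              "GCN": "use_gcn", "DCN": "use_dcn"}

__all__ = ["ModelConfig", "SeizureGraphModel", "ablate",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and ablation switches."""

    n_channels: int = 22          # N, electrode count
    n_features: int = 100         # C of the first block's input
    n_timesteps: int = 12         # T
    n_blocks: int = 2
    K: int = 3                    # Chebyshev terms (reach K-1 hops)
    gcn_channels: int = 64
    tcn_channels: int = 64
    dilation: int = 2
    kernel_size: int = 3
    fc_hidden: int = 64
    adjacency_mode: str = "correlation"
    use_tatt: bool = True
    use_satt: bool = True
    use_gcn: bool = True
    use_dcn: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_channels", "n_features", "n_timesteps", "n_blocks",
                     "K", "gcn_channels", "tcn_channels", "dilation",
                     "kernel_size", "fc_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def ablate(config: ModelConfig, module_name: str) -> ModelConfig:
    """Config with one of TAtt / SAtt / GCN / DCN switched off (idempotent)."""
    try:
        switch = _ABLATABLE[module_name]
    except KeyError:
        raise ValueError(f"unknown module {module_name!r}; "
                         f"expected one of {sorted(_ABLATABLE)}") from None
    return replace(config, **{switch: False})


class _Block:
    """One spatiotemporal block; owns its per-block parameters."""

    def __init__(self, rng: np.random.Generator, cfg: ModelConfig, c_in: int):
        N, T = cfg.n_channels, cfg.n_timesteps
        self.cfg = cfg
        # All parameter groups are drawn regardless of the ablation switches
        # so that an ablated model and the full model share the surviving
        # initial weights given the same seed (the switches then decide what
        # is kept and trained).
        tatt = TemporalAttentionParams.init(rng, N, c_in, T)
        satt = SpatialAttentionParams.init(rng, N, c_in, T)
        theta = [Tensor(ad.glorot_uniform(rng, (c_in, cfg.gcn_channels)),
                        requires_grad=True) for _ in range(cfg.K)]
        dcn = DilatedConvParams.init(rng, cfg.gcn_channels, cfg.tcn_channels,
                                     dilation=cfg.dilation,
                                     kernel_size=cfg.kernel_size)
        self.tatt = tatt if cfg.use_tatt else None
        self.satt = satt if cfg.use_satt else None
        self.theta = theta if cfg.use_gcn else theta[:1]
        if cfg.use_dcn:
            self.dcn = dcn
        else:  # width-1 convolution: keep only the center tap
            mid = cfg.kernel_size // 2
            self.dcn = DilatedConvParams(
                Phi=Tensor(dcn.Phi.data[:, :, mid:mid + 1].copy(),
                           requires_grad=True),
                bias=dcn.bias, dilation=1, kernel_size=1)

    def forward(self, X: Tensor, basis: list[np.ndarray],
                collect: dict | None = None,
                force_s_ones: bool = False) -> Tensor:
        if self.tatt is not None:
            E_norm, X = temporal_attention(X, self.tatt)
            if collect is not None:
                collect.setdefault("E_norm", []).append(E_norm.data)
        if self.satt is not None and not force_s_ones:
            S_norm = spatial_attention(X, self.satt)
            if collect is not None:
                collect.setdefault("S_norm", []).append(S_norm.data)
        else:
            S_norm = None
        if self.cfg.use_gcn:
            ones = np.ones((self.cfg.n_channels, self.cfg.n_channels))
            S = S_norm if S_norm is not None else Tensor(ones)
            Y = cheb_graph_conv(X, S, self.theta, basis)
        else:
            Y = einsum("bnct,co->bnot", X, self.theta[0])
        Y = Y.relu()
        return dilated_conv(Y, self.dcn).relu()

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.tatt is not None:
            out += self.tatt.tensors()
        if self.satt is not None:
            out += self.satt.tensors()
        out += self.theta
        out += self.dcn.tensors()
        return out


class SeizureGraphModel:
    """The assembled network: stacked blocks plus the FC head."""

    def __init__(self, config: ModelConfig, graph: GraphStructure):
        self.config = config
        self.graph = graph
        self.basis = chebyshev_basis(graph.L_tilde, config.K)
        rng = np.random.default_rng(config.seed)
        self.blocks: list[_Block] = []
        c_in = config.n_features
        for _ in range(config.n_blocks):
            self.blocks.append(_Block(rng, config, c_in))
            c_in = config.tcn_channels
        flat = config.n_channels * config.tcn_channels * config.n_timesteps
        self.W_fc = Tensor(ad.glorot_uniform(rng, (flat, config.fc_hidden)),
                           requires_grad=True)
        self.b_fc = Tensor(np.zeros(config.fc_hidden), requires_grad=True)
        self.W_out = Tensor(ad.glorot_uniform(rng, (config.fc_hidden, 1)),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(1), requires_grad=True)

    # ------------------------------------------------------------- forward
    def forward_logits(self, X: np.ndarray | Tensor,
                       collect: dict | None = None,
                       force_s_ones: bool = False) -> Tensor:
        """Pre-sigmoid scores, shape (B,). Input X: (B, N, C, T)."""
        if not isinstance(X, Tensor):
            X = Tensor(X)
        if X.ndim != 4:
            raise ValueError("X must be batched: (B, N, C, T)")
        B, N, C, T = X.shape
        cfg = self.config
        if (N, C, T) != (cfg.n_channels, cfg.n_features, cfg.n_timesteps):
            raise ValueError(
                f"input shape {(N, C, T)} does not match config "
                f"{(cfg.n_channels, cfg.n_features, cfg.n_timesteps)}")
        H = X
        for block in self.blocks:
            H = block.forward(H, self.basis, collect, force_s_ones)
        flat = H.reshape(B, -1)
        hidden = (einsum("bf,fh->bh", flat, self.W_fc) + self.b_fc).relu()
        logits = einsum("bh,ho->bo", hidden, self.W_out) + self.b_out
        return logits.reshape(B)

    def forward(self, X: np.ndarray | Tensor,
                collect: dict | None = None,
                force_s_ones: bool = False) -> np.ndarray:
        """Seizure probability per clip, each strictly inside (0, 1)."""
        p = self.forward_logits(X, collect, force_s_ones).sigmoid().data
        return np.clip(p, 1e-12, 1.0 - 1e-12)

    # ---------------------------------------------------------- parameters
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for b in self.blocks:
            out += b.tensors()
        out += [self.W_fc, self.b_fc, self.W_out, self.b_out]
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            a = np.asarray(arrays[f"param_{i}"])
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i}")
            p.data = a.astype(np.float64).copy()


def save_checkpoint(path, model: SeizureGraphModel,
                    norm_stats=None, extra: dict | None = None) -> None:
    """Weights + config (+ normalization stats) in one ``.npz`` bundle."""
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(model.config), "extra": extra or {}}
    arrays = dict(model.state_arrays())
    arrays["graph_A"] = model.graph.A
    if norm_stats is not None:
        arrays["norm_mean"] = norm_stats.mean
        arrays["norm_sd"] = norm_stats.sd
        meta["n_training_clips"] = int(norm_stats.n_training_clips)
    np.savez(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Return (model, norm_stats_or_None, meta)."""
    from .graph import normalized_scaled_laplacian
    from .preprocess import NormalizationStats

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"incompatible checkpoint format: {meta.get('format_version')}")
        config = ModelConfig(**meta["config"])
        graph = normalized_scaled_laplacian(z["graph_A"])
        model = SeizureGraphModel(config, graph)
        model.load_state_arrays(
            {k: z[k] for k in z.files if k.startswith("param_")})
        stats = None
        if "norm_mean" in z.files:
            stats = NormalizationStats(mean=z["norm_mean"], sd=z["norm_sd"],
                                       n_training_clips=meta.get(
                                           "n_training_clips", 0))
    return model, stats, meta
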