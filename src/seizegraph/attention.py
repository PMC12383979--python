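"""Temporal and spatial attention over the spectral EEG tensor.

Both maps are bilinear scores of the current layer input X in R^{N x C x T}
(N channels, C spectral features, T time steps), squashed by a sigmoid,
mixed by a learnable matrix, and row-normalized with a softmax:

  temporal   E = Ve . sigmoid( ((X^T U1) U2) (U3 X) + be ),   E' row-softmax, T x T
  spatial    S = Vs . sigmoid( ((X W1) W2) (W3 X)^T + bs ),   S' row-softmax, N x N

E' reweights the input along time (the (N*C) x T unfolding of X is
multiplied by E' on the right); S' modulates the graph convolution
element-wise.  S' is neither symmetrized, thresholded nor binarized: the
learned channel-to-channel influence is directed and dense by design.

Index contractions (batch axis b):
  temporal: lhs = einsum('bnct,n->btc', X, U1) @ U2 -> (b,t,n);
            rhs = einsum('c,bnct->bnt', U3, X); scores = lhs @ rhs -> (b,T,T)
  spatial:  lhs = einsum('bnct,t->bnc', X, W1) @ W2 -> (b,n,t);
            rhs = einsum('c,bnct->bnt', W3, X); scores = lhs @ rhs^T -> (b,N,N)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, einsum

__all__ = ["TemporalAttentionParams", "SpatialAttentionParams",
           "temporal_attention", "spatial_attention", "attention_maps_to_csv"]


def _init_mix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Near-identity init for the mixing matrices Ve/Vs (avoids saturating
    the sigmoid pathway at step 0 while keeping scores input-dependent)."""
    return np.eye(n) + 0.05 * rng.standard_normal((n, n))


@dataclass
class TemporalAttentionParams:
    """Learnable parameters of the T x T temporal attention."""

    Ve: Tensor
    be: Tensor
    U1: Tensor        # (N,)
    U2: Tensor        # (C, N)
    U3: Tensor        # (C,)

    @classmethod
    def init(cls, rng: np.random.Generator, N: int, C: int, T: int
             ) -> "TemporalAttentionParams":
        s = 1.0 / np.sqrt(C)
        return cls(
            Ve=Tensor(_init_mix(rng, T), requires_grad=True),
            be=Tensor(np.zeros((T, T)), requires_grad=True),
            U1=Tensor(rng.standard_normal(N) / np.sqrt(N), requires_grad=True),
            U2=Tensor(rng.standard_normal((C, N)) * s, requires_grad=True),
            U3=Tensor(rng.standard_normal(C) * s, requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [self.Ve, self.be, self.U1, self.U2, self.U3]


@dataclass
class SpatialAttentionParams:
    """Learnable parameters of the N x N spatial attention."""

    Vs: Tensor
    bs: Tensor
    W1: Tensor        # (T,)
    W2: Tensor        # (C, T)
    W3: Tensor        # (C,)

    @classmethod
    def init(cls, rng: np.random.Generator, N: int, C: int, T: int
             ) -> "SpatialAttentionParams":
        s = 1.0 / np.sqrt(C)
        return cls(
            Vs=Tensor(_init_mix(rng, N), requires_grad=True),
            bs=Tensor(np.zeros((N, N)), requires_grad=True),
            W1=Tensor(rng.standard_normal(T) / np.sqrt(T), requires_grad=True),
            W2=Tensor(rng.standard_normal((C, T)) * s, requires_grad=True),
            W3=Tensor(rng.standard_normal(C) * s, requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [self.Vs, self.bs, self.W1, self.W2, self.W3]


def temporal_attention(X: Tensor, params: TemporalAttentionParams
                       ) -> tuple[Tensor, Tensor]:
    """Return (E_norm, X_hat) for a batched input X of shape (B, N, C, T).

    E_norm is (B, T, T) and row-stochastic; X_hat has the shape of X and is
    the input reweighted along time by E_norm.
    """
    B, N, C, T = X.shape
    if params.U1.shape != (N,) or params.U2.shape != (C, N) \
            or params.U3.shape != (C,) or params.Ve.shape != (T, T):
        raise ValueError("temporal attention parameter shapes do not match input")
    lhs = einsum("btc,cn->btn", einsum("bnct,n->btc", X, params.U1), params.U2)
    rhs = einsum("c,bnct->bnt", params.U3, X)
    scores = einsum("btn,bns->bts", lhs, rhs)
    E = einsum("ij,bjk->bik", params.Ve, (scores + params.be).sigmoid())
    E_norm = E.softmax(axis=-1)
    X_flat = X.reshape(B, N * C, T)
    X_hat = einsum("bmj,bjt->bmt", X_flat, E_norm).reshape(B, N, C, T)
    return E_norm, X_hat


def spatial_attention(X: Tensor, params: SpatialAttentionParams) -> Tensor:
    """Return row-stochastic S_norm of shape (B, N, N) for X (B, N, C, T)."""
    B, N, C, T = X.shape
    if params.W1.shape != (T,) or params.W2.shape != (C, T) \
            or params.W3.shape != (C,) or params.Vs.shape != (N, N):
        raise ValueError("spatial attention parameter shapes do not match input")
    lhs = einsum("bnc,ct->bnt", einsum("bnct,t->bnc", X, params.W1), params.W2)
    rhs = einsum("c,bnct->bnt", params.W3, X)
    scores = einsum("bnt,bmt->bnm", lhs, rhs)
    S = einsum("ij,bjm->bim", params.Vs, (scores + params.bs).sigmoid())
    return S.softmax(axis=-1)


def attention_maps_to_csv(E_norm: np.ndarray, S_norm: np.ndarray,
                          e_path, s_path) -> None:
    """Write batch-mean attention maps as CSV heat-map tables."""
    import pandas as pd
    pd.DataFrame(np.asarray(E_norm).mean(axis=0)).to_csv(e_path, index=False)
    pd.DataFrame(np.asarray(S_norm).mean(axis=0)).to_csv(s_path, index=False)
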