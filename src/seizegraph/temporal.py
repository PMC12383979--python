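"""Dilated convolution along the time axis.

A 1-D convolution whose kernel taps are ``dilation - 1`` steps apart widens
the receptive field (reach ``(kernel_size - 1)/2 * dilation`` per layer for
odd kernels with symmetric zero padding) at constant parameter count; the
kernel is shared across the electrode axis.  Padding is chosen so the
temporal length is preserved exactly, which lets spatiotemporal blocks stack
without shape bookkeeping.  Clips are classified offline as whole segments,
so padding is symmetric rather than causal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, einsum

__all__ = ["DilatedConvParams", "dilated_conv"]


@dataclass
class DilatedConvParams:
    """Kernel stack Phi (C_in x C_out x kernel_size) plus geometry."""

    Phi: Tensor
    bias: Tensor          # (C_out,)
    dilation: int = 2
    kernel_size: int = 3

    def __post_init__(self):
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.Phi.shape[2] != self.kernel_size:
            raise ValueError("Phi trailing axis must equal kernel_size")

    @property
    def padding(self) -> int:
        # symmetric padding that preserves T for odd kernels
        return (self.kernel_size - 1) * self.dilation // 2

    @classmethod
    def init(cls, rng: np.random.Generator, c_in: int, c_out: int,
             dilation: int = 2, kernel_size: int = 3) -> "DilatedConvParams":
        Phi = ad.glorot_uniform(rng, (c_in, c_out, kernel_size),
                                fan_in=c_in * kernel_size, fan_out=c_out)
        return cls(Phi=Tensor(Phi, requires_grad=True),
                   bias=Tensor(np.zeros(c_out), requires_grad=True),
                   dilation=dilation, kernel_size=kernel_size)

    def tensors(self) -> list[Tensor]:
        return [self.Phi, self.bias]


def dilated_conv(X: Tensor, params: DilatedConvParams) -> Tensor:
    """Convolve (B, N, C_in, T) along T; returns (B, N, C_out, T).

    Zero-pads symmetrically, then sums kernel taps at offsets ``tau *
    dilation``; no activation is applied here (the call site applies ReLU).
    """
    if X.ndim != 4:
        raise ValueError("X must be (B, N, C, T)")
    if X.shape[2] != params.Phi.shape[0]:
        raise ValueError("input channel count does not match Phi")
    T = X.shape[3]
    pad = params.padding
    Xp = X.pad_last(pad, pad)
    out = None
    for tau in range(params.kernel_size):
        lo = tau * params.dilation
        seg = Xp[..., lo:lo + T]
        term = einsum("bnct,co->bnot", seg, params.Phi[:, :, tau])
        out = term if out is None else out + term
    return out + params.bias.reshape(1, 1, -1, 1)
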