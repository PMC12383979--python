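"""Graph machinery: adjacency construction, normalized/scaled Laplacians,
Chebyshev polynomial basis, and the attention-modulated spectral convolution.

The graph filter is the K-term Chebyshev approximation

    g_theta * x = sum_{k=0}^{K-1} theta_k T_k(L~) x,

with L~ = (2 / lambda_max) L_sym - I so the spectrum lies in [-1, 1], the
Chebyshev domain; K terms aggregate neighbors up to K-1 hops away.  The
dynamic variant modulates every basis matrix element-wise with the spatial
attention map S' (Hadamard product), which makes edge influence
input-dependent without re-deriving the Laplacian:

    y_t = sum_k (T_k(L~) ⊙ S') x_t theta_k.

With S' all ones the modulation is a no-op and the static filter is
recovered; a brute-force eigendecomposition oracle for that case lives here
too (tests compare both routes on small graphs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .montage import channel_position

logger = logging.getLogger(__name__)

__all__ = [
    "GraphStructure", "build_adjacency", "normalized_scaled_laplacian",
    "chebyshev_basis", "cheb_graph_conv", "spectral_filter_oracle",
    "adjacency_to_csv", "adjacency_from_csv",
]


@dataclass
class GraphStructure:
    """Static spectral-graph quantities derived from one adjacency."""

    A: np.ndarray
    D: np.ndarray
    L_sym: np.ndarray
    L_tilde: np.ndarray
    lambda_max: float


def build_adjacency(mode: str, *, n_channels: int | None = None,
                    channel_names: list[str] | None = None,
                    features: np.ndarray | None = None,
                    sigma: float = 0.5, kappa: float = 0.0) -> np.ndarray:
    """Base adjacency for the electrode graph.

    modes
      ``fully_connected``  all off-diagonal weights 1.
      ``distance_gaussian``  exp(-d^2 / sigma^2) of scalp distances between
        bipolar-channel midpoints, entries below ``kappa`` zeroed.
      ``correlation``  mean absolute Pearson correlation between channels'
        feature series over a training batch ``features`` of shape
        (clips, N, C, T); needs at least 2 clips.
    """
    if mode == "fully_connected":
        if n_channels is None:
            n_channels = len(channel_names) if channel_names else None
        if not n_channels:
            raise ValueError("fully_connected mode needs n_channels")
        A = np.ones((n_channels, n_channels))
    elif mode == "distance_gaussian":
        if not channel_names:
            raise ValueError("distance_gaussian mode needs channel_names")
        xy = np.stack([channel_position(c) for c in channel_names])
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        A = np.exp(-d2 / sigma ** 2)
        A[A < kappa] = 0.0
    elif mode == "correlation":
        if features is None or features.ndim != 4 or features.shape[0] < 2:
            raise ValueError(
                "correlation mode needs a (clips, N, C, T) batch with >= 2 clips")
        B, N = features.shape[:2]
        acc = np.zeros((N, N))
        for b in range(B):
            series = features[b].reshape(N, -1)
            sd = series.std(axis=1)
            sd[sd == 0] = 1.0
            z = (series - series.mean(axis=1, keepdims=True)) / sd[:, None]
            acc += np.abs(z @ z.T / series.shape[1])
        A = acc / B
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(A, 0.0)
    return 0.5 * (A + A.T)


def normalized_scaled_laplacian(A: np.ndarray,
                                lambda_max_exact: bool = True) -> GraphStructure:
    """L_sym = I - D^{-1/2} A D^{-1/2};  L~ = (2/lambda_max) L_sym - I.

    ``lambda_max`` comes from an exact symmetric eigensolve (electrode graphs
    are tiny); set ``lambda_max_exact=False`` for the common lambda_max = 2
    shortcut.  Isolated nodes get D^{-1/2} = 0 with a warning.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T):
        raise ValueError("A must be symmetric")
    if (A < 0).any():
        raise ValueError("A must be nonnegative")
    deg = A.sum(axis=1)
    if (deg == 0).any():
        logger.warning("adjacency has %d isolated node(s); their D^{-1/2} "
                       "entries are set to 0", int((deg == 0).sum()))
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, deg ** -0.5, 0.0)
    N = A.shape[0]
    L_sym = np.eye(N) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    L_sym = 0.5 * (L_sym + L_sym.T)
    lam = float(np.linalg.eigvalsh(L_sym)[-1]) if lambda_max_exact else 2.0
    if lam <= 0:
        lam = 2.0  # edgeless graph: L_sym has only zero eigenvalues
    L_tilde = (2.0 / lam) * L_sym - np.eye(N)
    return GraphStructure(A=A, D=np.diag(deg), L_sym=L_sym,
                          L_tilde=L_tilde, lambda_max=lam)


def chebyshev_basis(L_tilde: np.ndarray, K: int) -> list[np.ndarray]:
    """[T_0, ..., T_{K-1}] with T_0 = I, T_1 = L~, T_k = 2 L~ T_{k-1} - T_{k-2}."""
    if K < 1:
        raise ValueError("K must be >= 1")
    N = L_tilde.shape[0]
    basis = [np.eye(N)]
    if K > 1:
        basis.append(L_tilde.copy())
    for _ in range(2, K):
        basis.append(2.0 * L_tilde @ basis[-1] - basis[-2])
    return basis


def cheb_graph_conv(X: ad.Tensor, S_norm: ad.Tensor | np.ndarray,
                    theta: list[ad.Tensor],
                    basis: list[np.ndarray]) -> ad.Tensor:
    """Attention-modulated Chebyshev filtering of a batched tensor.

    X: (B, N, C_in, T); S_norm: (B, N, N) or (N, N); theta: K tensors of
    shape (C_in, C_out).  Returns (B, N, C_out, T).
    """
    if len(theta) != len(basis):
        raise ValueError("kernel order K does not match Chebyshev basis")
    if X.ndim != 4:
        raise ValueError("X must be (B, N, C, T)")
    if not isinstance(S_norm, ad.Tensor):
        S_norm = ad.Tensor(S_norm)
    out = None
    for Tk, th in zip(basis, theta):
        Mk = S_norm * ad.Tensor(Tk)               # Hadamard modulation
        if Mk.ndim == 2:
            Zk = ad.einsum("nm,bmct->bnct", Mk, X)
        else:
            Zk = ad.einsum("bnm,bmct->bnct", Mk, X)
        term = ad.einsum("bnct,co->bnot", Zk, th)
        out = term if out is None else out + term
    return out


def spectral_filter_oracle(X: np.ndarray, theta: list[np.ndarray],
                           graph: GraphStructure) -> np.ndarray:
    """Brute-force spectral route for the unmodulated filter (S' = ones).

    Transforms into the graph Fourier basis of L~ (x_hat = U^T x), applies
    the polynomial filter on the eigenvalues, transforms back — the textbook
    definition the Chebyshev recursion approximates exactly for polynomial
    filters.  X: (B, N, C_in, T); theta: K arrays (C_in, C_out).
    """
    lam, U = np.linalg.eigh(graph.L_tilde)
    out = None
    for k, th in enumerate(theta):
        # Chebyshev polynomial evaluated on the eigenvalues
        filt = np.cos(k * np.arccos(np.clip(lam, -1.0, 1.0)))
        Xhat = np.einsum("mn,bmct->bnct", U, X)           # U^T x
        Y = np.einsum("nm,bmct->bnct", U * filt[None, :], Xhat)  # U diag(f) x_hat
        term = np.einsum("bnct,co->bnot", Y, th)
        out = term if out is None else out + term
    return out


def adjacency_to_csv(A: np.ndarray, channel_names: list[str], path) -> None:
    """Edge-weight matrix as CSV with a channel-name header row."""
    import pandas as pd
    pd.DataFrame(A, index=list(channel_names),
                 columns=list(channel_names)).to_csv(path)


def adjacency_from_csv(path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.columns)
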