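"""Style-removal primitives: instance normalization and instance whitening.

Instance normalization (IN) standardises each channel of each sample by its
own spatial statistics, stripping per-image "style" (stain intensity,
contrast).  Instance whitening (IW) penalises the deviation of a sample's
channel-covariance matrix from the identity, removing inter-channel
correlation.  Both use the population convention (divisor H*W).

All functions accept either plain NumPy arrays or autodiff
:class:`~unwseg.autodiff.Tensor` objects; in the latter case they are fully
differentiable and are the exact code path used inside training losses.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["instance_normalize", "channel_covariance",
           "batched_channel_covariance", "iw_loss", "covariance_oracle",
           "DEFAULT_BETA"]

#: default numerical stabiliser added to the variance before the square root
DEFAULT_BETA = 1e-5


def _raw(x):
    """Underlying ndarray of a Tensor, or the array itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _check_4d(F):
    if _raw(F).ndim != 4:
        raise ValueError("expected a 4-D (N, K, H, W) feature map, got "
                         f"shape {_raw(F).shape}")


def instance_normalize(F, beta=DEFAULT_BETA, validate=True):
    """Per-sample, per-channel spatial standardization.

    Each channel of each sample is shifted to spatial mean 0 and scaled by
    1/sqrt(var + beta), var the population variance over the H*W positions.

    Parameters
    ----------
    F : (N, K, H, W) array or Tensor
    beta : float
        Nonnegative stabiliser.  With ``beta = 0`` a spatially constant
        channel is a division by zero and raises instead of producing NaN.
    validate : bool
        Skip the finiteness check (used inside training loops, where a
        non-finite value must surface as a divergence diagnostic rather
        than an input error).
    """
    _check_4d(F)
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    raw = _raw(F)
    if validate and not np.all(np.isfinite(raw)):
        raise ValueError("feature map contains non-finite values")
    mu = F.mean(axis=(2, 3), keepdims=True)
    var = ((F - mu) ** 2).mean(axis=(2, 3), keepdims=True)
    if beta == 0 and np.any(_raw(var) == 0):
        raise ZeroDivisionError(
            "constant channel with beta = 0: variance vanishes")
    return (F - mu) / (var + beta) ** 0.5


def channel_covariance(F, n):
    """K x K channel covariance of sample ``n`` (population, divisor H*W).

    Entry (j, k) is the spatial covariance between channels j and k of the
    sample, computed about each channel's own spatial mean.
    """
    _check_4d(F)
    N, K, H, W = _raw(F).shape
    if not 0 <= n < N:
        raise IndexError(f"sample index {n} out of range for N={N}")
    X = F[n].reshape(K, H * W)
    Xc = X - X.mean(axis=1, keepdims=True)
    return (Xc @ Xc.transpose(1, 0)) * (1.0 / (H * W))


def batched_channel_covariance(F):
    """(N, K, K) stack of per-sample channel covariances."""
    _check_4d(F)
    N, K, H, W = _raw(F).shape
    X = F.reshape(N, K, H * W)
    Xc = X - X.mean(axis=2, keepdims=True)
    return (Xc @ Xc.transpose(0, 2, 1)) * (1.0 / (H * W))


def iw_loss(F):
    """Instance-whitening loss: sum over samples of ||Sigma_n - I||_1.

    The norm is entrywise (sum of absolute values of all K^2 entries), so
    the loss is zero exactly when every sample's channel covariance is the
    identity.
    """
    _check_4d(F)
    K = _raw(F).shape[1]
    eye = np.eye(K, dtype=_raw(F).dtype)
    cov = batched_channel_covariance(F)
    return abs(cov - eye).sum()


def covariance_oracle(F, n):
    """Loop-based reference for :func:`channel_covariance` (tests only).

    Explicit nested loops over channels and pixels; guarded to small inputs.
    """
    F = np.asarray(_raw(F), dtype=np.float64)
    _check_4d(F)
    N, K, H, W = F.shape
    if K > 16 or H * W > 256:
        raise ValueError("oracle restricted to K <= 16 and H*W <= 256")
    if not 0 <= n < N:
        raise IndexError("sample index out of range")
    mu = np.zeros(K)
    for j in range(K):
        s = 0.0
        for h in range(H):
            for w in range(W):
                s += F[n, j, h, w]
        mu[j] = s / (H * W)
    cov = np.zeros((K, K))
    for j in range(K):
        for k in range(K):
            s = 0.0
            for h in range(H):
                for w in range(W):
                    s += (F[n, j, h, w] - mu[j]) * (F[n, k, h, w] - mu[k])
            cov[j, k] = s / (H * W)
    return cov
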