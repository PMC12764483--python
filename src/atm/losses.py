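"""Training loss components: Dice segmentation, beta-VAE, point-adjacency.

Every function works both on plain numpy arrays (returning floats, used by
tests and evaluation) and on autodiff :class:`~atm.nn.Tensor` objects (used
by the training loop); the arithmetic is written once in terms of the shared
operator surface.

Conventions, fixed here and documented in the methods note:

* the squared reconstruction error is the *sum* over all K x 3 coordinate
  entries of a streamline (not the per-point mean);
* the KL divergence of the diagonal-Gaussian posterior from the standard
  normal prior uses the closed form
  ``0.5 * sum_d(mu_d^2 + sigma_d^2 - 1 - 2 log sigma_d)``;
* the adjacency penalty averages consecutive-point distances within each
  streamline over the K - 1 existing pairs, then adds the batch mean and
  batch max of these per-streamline averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from atm.nn.tensor import Tensor


@dataclass
class LossWeights:
    """Weights of the total loss; defaults are the reference settings."""

    lambda_seg: float = 1.0
    lambda_vae: float = 1.0
    lambda_adj: float = 1.0
    beta: float = 1.0
    dice_smoothing: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("lambda_seg", "lambda_vae", "lambda_adj", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dice_smoothing <= 0:
            raise ValueError("dice_smoothing must be positive")


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def _maybe_float(x):
    """Scalar numpy results become floats; tensors keep their graph."""
    return x if isinstance(x, Tensor) else float(x)


def dice_segmentation_loss(gt, pred, e: float = 1e-6):
    """Smoothed soft-Dice loss between a binary target and a [0,1] prediction.

    ``1 - 2 (sum gt*pred + e) / (sum gt^2 + sum pred^2 + e)``.
    """
    gt_data = gt.data if isinstance(gt, Tensor) else np.asarray(gt)
    pred_shape = pred.shape if isinstance(pred, Tensor) else np.asarray(pred).shape
    if tuple(gt_data.shape) != tuple(pred_shape):
        raise ValueError(f"grid mismatch: gt {gt_data.shape} vs pred {pred_shape}")
    if e <= 0:
        raise ValueError("smoothing constant e must be positive")
    inter = (gt * pred).sum()
    denom = (gt * gt).sum() + (pred * pred).sum() + e
    loss = 1.0 - 2.0 * (inter + e) / denom
    return _maybe_float(loss)


def kl_diag_gaussian(mu, sigma):
    """Closed-form KL( N(mu, diag sigma^2) || N(0, I) ), summed over dims.

    For batched inputs (N, D) returns the per-sample KL of shape (N,).
    """
    sig_data = sigma.data if isinstance(sigma, Tensor) else np.asarray(sigma)
    if np.any(sig_data <= 0):
        raise ValueError("sigma must be strictly positive")
    term = mu * mu + sigma * sigma - 1.0 - 2.0 * _log(sigma)
    axis = -1
    return 0.5 * term.sum(axis=axis)


def vae_loss(s_batch, s_recon, mu, sigma=None, beta: float = 1.0):
    """Mean over the batch of (reconstruction SSE + beta * KL).

    ``s_batch`` and ``s_recon`` are (N, K, 3); ``mu``/``sigma`` are (N, D).
    A posterior object with ``mu``/``sigma`` attributes may be passed in
    place of the two arrays.
    """
    if sigma is None:
        mu, sigma = mu.mu, mu.sigma
    diff = s_batch - s_recon
    n = diff.shape[0]
    sse = (diff * diff).reshape(n, -1).sum(axis=1)  # (N,)
    kl = kl_diag_gaussian(mu, sigma)  # (N,)
    total = (sse + beta * kl).sum() * (1.0 / n)
    return _maybe_float(total)


def adjacency_regularizer(s_batch):
    """Mean plus max over streamlines of the average consecutive-point gap.

    ``s_batch`` is (N, K, 3) with K >= 2.  Zero iff all points of every
    streamline coincide.
    """
    shape = s_batch.shape
    if len(shape) != 3 or shape[1] < 2:
        raise ValueError("adjacency regularizer needs (N, K>=2, 3) input")
    n, k, _ = shape
    if isinstance(s_batch, Tensor):
        deltas = s_batch[:, 1:, :] - s_batch[:, :-1, :]
    else:
        s_batch = np.asarray(s_batch, dtype=np.float64)
        deltas = s_batch[:, 1:, :] - s_batch[:, :-1, :]
    dist = _sqrt((deltas * deltas).sum(axis=-1))  # (N, K-1)
    b = dist.sum(axis=1) * (1.0 / (k - 1))  # (N,)
    loss = b.mean() + b.max()
    return _maybe_float(loss)


def total_loss(l_seg, l_vae, l_adj, weights: LossWeights):
    """Weighted sum of the three components."""
    out = (
        weights.lambda_seg * l_seg
        + weights.lambda_vae * l_vae
        + weights.lambda_adj * l_adj
    )
    return _maybe_float(out)
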