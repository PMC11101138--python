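"""Training objectives: MSE reconstruction, Gaussian KL, and l1 activity.

Three composite losses are used across the five architectures:

* ``L1 = MSE`` — plain reconstruction error (AE-Decoder and Direct
  Convolutional, and the fully-connected-mapper reverse path);
* ``L2 = MSE + KL[Q(z|X) || N(0, I)]`` — the variational autoencoding
  objective (forward paths of the VAE variants, reverse path of the
  VAE-Sampler-Decoder);
* ``L3 = MSE + KL[Q(z|y) || N(0, I)]`` — the same arithmetic with the
  posterior conditioned on the muscle vector (Direct Variational).

MSE sums the squared error per sample and averages over the batch (not a
per-voxel mean); the KL term is likewise a batch mean, so the two terms share
the 1/N normalisation. ``per_voxel=True`` switches to the per-voxel mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossReport", "mse_loss", "kl_gaussian", "loss_l2", "loss_l3",
           "l1_penalty"]


@dataclass
class LossReport:
    total: float
    mse_term: float
    kl_term: float = 0.0
    l1_term: float = 0.0


def mse_loss(pred: np.ndarray, gt: np.ndarray, per_voxel: bool = False) -> float:
    """(1/N) sum_i ||pred_i - gt_i||_2^2 over a batch of volumes."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    n = pred.shape[0]
    sq = float(((pred - gt) ** 2).sum())
    if per_voxel:
        return sq / pred.size
    return sq / n


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), batch-averaged if 2D.

    Closed form per sample: ``0.5 * sum_n [exp(lv) + mu^2 - 1 - lv]``;
    nonnegative, zero iff mu = 0 and logvar = 0.
    """
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError("mu and logvar must have the same shape")
    per = 0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar)
    n = mu.shape[0] if mu.ndim == 2 else 1
    return float(per) / n


def loss_l2(pred: np.ndarray, gt: np.ndarray,
            mu_x: np.ndarray, logvar_x: np.ndarray,
            l1_term: float = 0.0) -> LossReport:
    """MSE + KL with the posterior conditioned on the volume X."""
    mse = mse_loss(pred, gt)
    kl = kl_gaussian(mu_x, logvar_x)
    return LossReport(total=mse + kl + l1_term, mse_term=mse, kl_term=kl,
                      l1_term=l1_term)


def loss_l3(pred: np.ndarray, gt: np.ndarray,
            mu_y: np.ndarray, logvar_y: np.ndarray,
            l1_term: float = 0.0) -> LossReport:
    """MSE + KL with the posterior conditioned on the muscle vector y.

    Identical arithmetic to ``loss_l2``; only the conditioning differs.
    """
    return loss_l2(pred, gt, mu_y, logvar_y, l1_term=l1_term)


def l1_penalty(target: np.ndarray, weight: float = 1e-4) -> float:
    """weight * sum |t| — sparsity penalty on the (pre-mask) reconstruction."""
    return float(weight * np.abs(np.asarray(target, dtype=np.float64)).sum())
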