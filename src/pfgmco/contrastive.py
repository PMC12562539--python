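"""Model-contrastive loss between aggregated, local, and previous encoders.

On the same input volume, three feature vectors are extracted: ``f_fed``
from the freshly aggregated encoder, ``f_local`` from the locally updated
encoder of this round, and ``f_pre`` from the previous round's encoder.
The loss pulls the aggregated representation toward the local one and away
from last round's, steering personalization.

Two variants are provided.  ``as_printed`` uses similarity in the numerator
and (1 - cos) distances in the denominator,

    L = -log( exp[cos(f_fed,f_local)/tau]
              / (exp[(1-cos(f_fed,f_local))/tau] + exp[(1-cos(f_fed,f_pre))/tau]) ),

while ``moon`` is the standard model-contrastive (MOON) form with
similarities throughout the denominator.  ``as_printed`` is the default;
the asymmetry between its numerator and denominator is documented rather
than silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ContrastiveConfig", "contrastive_loss", "contrastive_loss_and_grad"]

VARIANTS = ("as_printed", "moon")


@dataclass(frozen=True)
class ContrastiveConfig:
    tau: float = 0.5
    variant: str = "as_printed"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def _as_batch(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    return f[None] if f.ndim == 1 else f


def _cos_and_grad(u: np.ndarray, v: np.ndarray):
    """Row-wise cosine and its gradient w.r.t. ``u``."""
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("degenerate zero-norm feature in contrastive loss")
    c = (u * v).sum(axis=1, keepdims=True) / (nu * nv)
    dc_du = v / (nu * nv) - c * u / nu ** 2
    return c[:, 0], dc_du


def _loss_terms(c1: np.ndarray, c2: np.ndarray, cfg: ContrastiveConfig):
    """Per-sample loss and (dL/dc1, dL/dc2)."""
    t = cfg.tau
    if cfg.variant == "as_printed":
        a = np.stack([(1 - c1) / t, (1 - c2) / t], axis=1)
        lse = logsumexp(a, axis=1)
        loss = -c1 / t + lse
        w = np.exp(a - lse[:, None])  # softmax over the two denominator terms
        dl_dc1 = -1 / t - w[:, 0] / t
        dl_dc2 = -w[:, 1] / t
    else:  # moon
        a = np.stack([c1 / t, c2 / t], axis=1)
        lse = logsumexp(a, axis=1)
        loss = -c1 / t + lse
        w = np.exp(a - lse[:, None])
        dl_dc1 = (-1 + w[:, 0]) / t
        dl_dc2 = w[:, 1] / t
    return loss, dl_dc1, dl_dc2


def contrastive_loss(f_fed: np.ndarray, f_local: np.ndarray, f_pre: np.ndarray,
                     cfg: ContrastiveConfig = ContrastiveConfig()) -> float:
    """Mean contrastive loss over the batch (scalar for single vectors)."""
    loss, _ = contrastive_loss_and_grad(f_fed, f_local, f_pre, cfg)
    return loss


def contrastive_loss_and_grad(f_fed: np.ndarray, f_local: np.ndarray,
                              f_pre: np.ndarray,
                              cfg: ContrastiveConfig = ContrastiveConfig(),
                              ) -> tuple[float, np.ndarray]:
    """Batch-mean loss and its gradient w.r.t. ``f_fed``.

    ``f_local`` and ``f_pre`` come from frozen encoder snapshots and are
    treated as constants.
    """
    ff, fl, fp = _as_batch(f_fed), _as_batch(f_local), _as_batch(f_pre)
    c1, dc1 = _cos_and_grad(ff, fl)
    c2, dc2 = _cos_and_grad(ff, fp)
    loss, dl_dc1, dl_dc2 = _loss_terms(c1, c2, cfg)
    n = ff.shape[0]
    grad = (dl_dc1[:, None] * dc1 + dl_dc2[:, None] * dc2) / n
    if np.asarray(f_fed).ndim == 1:
        grad = grad[0]
    return float(loss.mean()), grad
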