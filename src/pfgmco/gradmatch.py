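"""Gradient matching: cross-client similarity from GM-head gradients.

Protocol per round, for recipient client *i*:

1. *i* noises and broadcasts its GM-head parameters.
2. Every peer *j* encodes its own volumes locally, evaluates the mean
   cross-entropy gradient of *i*'s (noised) head on those features, noises
   the gradient, and returns it.  Raw data and labels never move.
3. *i* computes a pair loss ``1 - cos(g_i, g_j)`` per peer and converts the
   losses into aggregation weights ``lambda_{i,j}`` summing to one.

Two weighting modes exist because the printed weight definition
(``lambda = L_ij / sum L_ij``) favours *dissimilar* peers while the
surrounding narrative favours similar ones; ``similarity`` (the default)
uses the complement ``(2 - L_ij)`` and matches the stated intent, while
``as_printed`` reproduces the formula literally.

GM-head gradients are laid out as the flattened augmented matrix
``[W | b]`` of shape ``(2, d_feat + 1)`` throughout.
"""

from __future__ import annotations

import numpy as np

from .nn import softmax
from .privacy import NoiseConfig, gaussian_mechanism

__all__ = [
    "head_gradient",
    "head_hessian",
    "gm_pair_loss",
    "client_gradients",
    "adaptive_weights",
    "WEIGHT_MODES",
]

WEIGHT_MODES = ("as_printed", "similarity")


def _augment(features: np.ndarray) -> np.ndarray:
    return np.hstack([features, np.ones((features.shape[0], 1))])


def head_gradient(head_wb: np.ndarray, features: np.ndarray,
                  labels: np.ndarray) -> np.ndarray:
    """Mean cross-entropy gradient of a linear head w.r.t. its parameters.

    Closed form for softmax-CE: ``grad = mean_k (p_k - onehot(y_k)) phi_k^T``
    with ``phi = [f, 1]``.  Returns the flattened ``(2, d+1)`` matrix.
    """
    if features.shape[1] + 1 != head_wb.shape[1]:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match head "
            f"dim {head_wb.shape[1] - 1}")
    phi = _augment(features)
    p = softmax(phi @ head_wb.T)
    p[np.arange(len(labels)), labels] -= 1.0
    return (p.T @ phi / len(labels)).ravel()


def head_hessian(head_wb: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Mean CE Hessian of the linear head, shape ``(2(d+1), 2(d+1))``.

    Per sample the Hessian is ``kron(diag(p) - p p^T, phi phi^T)``, which
    matches the row-major ``[W | b]`` flattening used by `head_gradient`.
    """
    phi = _augment(features)
    p = softmax(phi @ head_wb.T)
    n, m = phi.shape
    H = np.zeros((2 * m, 2 * m))
    for k in range(n):
        A = np.diag(p[k]) - np.outer(p[k], p[k])
        H += np.kron(A, np.outer(phi[k], phi[k]))
    return H / n


def gm_pair_loss(g_i: np.ndarray, g_j_noised: np.ndarray) -> float:
    """Gradient-matching pair loss ``1 - cos(g_i, g_j)``, in [0, 2]."""
    ni, nj = np.linalg.norm(g_i), np.linalg.norm(g_j_noised)
    if ni == 0 or nj == 0:
        raise ValueError("degenerate zero-norm gradient in gm_pair_loss")
    return float(1.0 - g_i @ g_j_noised / (ni * nj))


def client_gradients(head_wb_noised: np.ndarray,
                     features_by_client: dict[object, np.ndarray],
                     labels_by_client: dict[object, np.ndarray],
                     noise_by_client: dict[object, NoiseConfig] | None = None,
                     ) -> dict[object, np.ndarray]:
    """Each peer's mean CE gradient of the recipient's noised head.

    The gradient is evaluated on the peer's own locally encoded features and
    labels, then passed through that peer's Gaussian mechanism before it
    crosses the client boundary.
    """
    out = {}
    for cid, feats in features_by_client.items():
        g = head_gradient(head_wb_noised, feats, labels_by_client[cid])
        if noise_by_client is not None:
            g = gaussian_mechanism(g, noise_by_client[cid])
        out[cid] = g
    return out


def adaptive_weights(pair_losses: dict[object, float],
                     mode: str = "similarity") -> dict[object, float]:
    """Normalize pair losses into aggregation weights summing to one."""
    if mode not in WEIGHT_MODES:
        raise ValueError(f"mode must be one of {WEIGHT_MODES}, got {mode!r}")
    if not pair_losses:
        raise ValueError("adaptive_weights needs at least one peer")
    for cid, loss in pair_losses.items():
        if not (-1e-9 <= loss <= 2 + 1e-9):
            raise ValueError(f"pair loss for {cid!r} outside [0, 2]: {loss}")
    if mode == "as_printed":
        raw = {cid: max(loss, 0.0) for cid, loss in pair_losses.items()}
    else:
        raw = {cid: max(2.0 - loss, 0.0) for cid, loss in pair_losses.items()}
    total = sum(raw.values())
    if total == 0:
        raise ValueError(f"all-zero weight denominator in mode {mode!r}")
    return {cid: v / total for cid, v in raw.items()}
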