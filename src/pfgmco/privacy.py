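"""Gaussian-noise mechanism applied to every cross-client exchange.

Any information leaving a client — model parameters during aggregation,
GM-head parameters broadcast for gradient matching, and the gradients
returned by peers — is perturbed by additive zero-mean Gaussian noise of
variance ``sigma2`` *by the sender*, so a recipient never observes clean
values.  ``sigma2`` trades privacy against utility; the working default is
0.001.  No sensitivity calibration or formal (epsilon, delta) accounting is
performed: the mechanism is plain additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseConfig", "gaussian_mechanism"]

DEFAULT_SIGMA2 = 0.001


@dataclass
class NoiseConfig:
    """Noise variance and random stream for one client's outgoing messages."""

    sigma2: float = DEFAULT_SIGMA2
    seed: int | None = None

    def __post_init__(self):
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        self._rng = np.random.default_rng(self.seed)

    @property
    def rng(self) -> np.random.Generator:
        return self._rng


def gaussian_mechanism(p: np.ndarray, cfg: NoiseConfig) -> np.ndarray:
    """Return ``p + N(0, sigma2)`` elementwise; the input is not modified.

    With ``sigma2 == 0`` the output equals the input exactly.  Noise is drawn
    fresh from ``cfg``'s stream on every call (one draw per exchange).
    """
    p = np.asarray(p)
    if not np.issubdtype(p.dtype, np.floating):
        p = p.astype(float)
    if not np.all(np.isfinite(p)):
        raise ValueError("shared information must be finite")
    if cfg.sigma2 == 0:
        return p.copy()
    noise = cfg.rng.normal(0.0, np.sqrt(cfg.sigma2), size=p.shape)
    return p + noise.astype(p.dtype)
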