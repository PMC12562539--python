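"""Multimodal compact bilinear (MCB) pooling.

Bilinear pooling of two feature vectors is the outer product ``a b^T`` —
quadratically large.  MCB approximates it compactly: each vector is count-
sketched (random signed hashing, the projection Phi), and the sketch of the
outer product equals the *circular convolution* of the two sketches, which
is computed in O(d log d) via FFT:

    MCB(a, b) = IFFT( FFT(Phi(a)) * FFT(Phi(b)) )

Three modalities are fused hierarchically: the two functional channels
(ALFF, ReHo) first, then the result with the structural features.  Each
fusion site uses its own independently drawn sketches; hashes are fixed at
model-build time and persisted with checkpoints, since fusion is meaningless
if they change between training and test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SketchSpec",
    "TrimodalSketchSpecs",
    "make_sketch_spec",
    "make_trimodal_specs",
    "count_sketch",
    "mcb_pool",
    "fuse_trimodal",
]


@dataclass(frozen=True)
class SketchSpec:
    """Count-sketch hash table: index h[i] in [0, d_out) and sign s[i]."""

    d_in: int
    d_out: int
    h: np.ndarray
    s: np.ndarray
    seed: int

    def __post_init__(self):
        if len(self.h) != self.d_in or len(self.s) != self.d_in:
            raise ValueError("h and s must have length d_in")


def make_sketch_spec(d_in: int, d_out: int, seed: int) -> SketchSpec:
    rng = np.random.default_rng(seed)
    h = rng.integers(0, d_out, size=d_in)
    s = rng.choice(np.array([-1.0, 1.0]), size=d_in)
    return SketchSpec(d_in, d_out, h, s, seed)


def count_sketch(x: np.ndarray, spec: SketchSpec) -> np.ndarray:
    """Signed-hash projection: ``out[k] = sum_{i: h[i]=k} s[i] * x[i]``."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = x[None] if single else x
    if xb.shape[1] != spec.d_in:
        raise ValueError(f"input dim {xb.shape[1]} != spec d_in {spec.d_in}")
    out = np.zeros((xb.shape[0], spec.d_out))
    np.add.at(out, (slice(None), spec.h), xb * spec.s)
    return out[0] if single else out


def mcb_pool(a: np.ndarray, b: np.ndarray, spec_a: SketchSpec,
             spec_b: SketchSpec, normalize: bool = False) -> np.ndarray:
    """Compact bilinear pooling of two vectors (or batches of vectors).

    Equals the circular convolution of the two count sketches; the
    imaginary residue of the inverse FFT is checked to be numerically nil
    before the real part is returned.  With ``normalize=True`` the common
    signed-square-root + l2 post-processing is applied (off by default).
    """
    if spec_a.d_out != spec_b.d_out:
        raise ValueError(
            f"sketch output dims differ: {spec_a.d_out} != {spec_b.d_out}")
    sa, sb = count_sketch(a, spec_a), count_sketch(b, spec_b)
    z = np.fft.ifft(np.fft.fft(sa, axis=-1) * np.fft.fft(sb, axis=-1), axis=-1)
    resid = np.abs(z.imag).max() if z.size else 0.0
    scale = max(np.abs(z.real).max(), 1.0)
    if resid > 1e-6 * scale:
        raise FloatingPointError(f"non-real MCB output (residue {resid:.2e})")
    out = z.real
    if normalize:
        out = np.sign(out) * np.sqrt(np.abs(out))
        norm = np.linalg.norm(out, axis=-1, keepdims=True)
        out = np.divide(out, norm, out=np.zeros_like(out), where=norm > 0)
    return out


@dataclass(frozen=True)
class TrimodalSketchSpecs:
    """Sketches for the two fusion sites: (ALFF x ReHo), then (sMRI x func)."""

    alff: SketchSpec
    reho: SketchSpec
    smri: SketchSpec
    func: SketchSpec  # applied to the ALFF x ReHo fusion output


def make_trimodal_specs(d_smri: int, d_alff: int, d_reho: int, d_out: int,
                        seed: int) -> TrimodalSketchSpecs:
    ss = np.random.SeedSequence([int(seed), 0x5EC7])
    seeds = [int(s) for s in ss.generate_state(4)]
    return TrimodalSketchSpecs(
        alff=make_sketch_spec(d_alff, d_out, seeds[0]),
        reho=make_sketch_spec(d_reho, d_out, seeds[1]),
        smri=make_sketch_spec(d_smri, d_out, seeds[2]),
        func=make_sketch_spec(d_out, d_out, seeds[3]),
    )


def fuse_trimodal(f_s: np.ndarray, f_a: np.ndarray, f_r: np.ndarray,
                  specs: TrimodalSketchSpecs,
                  normalize: bool = False) -> np.ndarray:
    """Hierarchical fusion ``MCB(f_s, MCB(f_a, f_r))`` -> length d_out."""
    z_func = mcb_pool(f_a, f_r, specs.alff, specs.reho, normalize=normalize)
    return mcb_pool(f_s, z_func, specs.smri, specs.func, normalize=normalize)
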