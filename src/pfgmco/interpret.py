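"""Interpretability: occlusion-sensitivity maps and ROI group statistics.

An occlusion map localizes the discriminative evidence a trained 3D
classifier uses: volumetric patches of the input are zeroed one grid
position at a time, and the decrease in prediction accuracy relative to the
unoccluded baseline is recorded — a larger drop means a more discriminative
region.  A companion utility tests per-ROI group differences with Welch's
two-sample t-test and Benjamini–Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["OcclusionMap", "occlusion_map", "group_difference_map"]


@dataclass
class OcclusionMap:
    """Accuracy drop per occluded patch, on the patch grid."""

    drops: np.ndarray                 # (n_z, n_y, n_x)
    starts: tuple[np.ndarray, ...]    # grid start coordinate per axis
    patch_size: tuple[int, int, int]
    stride: tuple[int, int, int]
    baseline_acc: float

    def to_voxel_map(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Broadcast patch drops to voxel resolution (mean over covering
        patches)."""
        total = np.zeros(shape)
        count = np.zeros(shape)
        for iz, z0 in enumerate(self.starts[0]):
            for iy, y0 in enumerate(self.starts[1]):
                for ix, x0 in enumerate(self.starts[2]):
                    sl = tuple(slice(s, s + p) for s, p in
                               zip((z0, y0, x0), self.patch_size))
                    total[sl] += self.drops[iz, iy, ix]
                    count[sl] += 1
        return np.divide(total, count, out=np.zeros(shape), where=count > 0)

    def top_decile_threshold(self) -> float:
        return float(np.quantile(self.drops, 0.9))


def _axis_starts(size: int, patch: int, stride: int) -> np.ndarray:
    if patch > size:
        raise ValueError(f"patch size {patch} exceeds volume axis {size}")
    starts = list(range(0, size - patch + 1, max(stride, 1)))
    if starts[-1] != size - patch:  # make sure the far edge is covered
        starts.append(size - patch)
    return np.array(starts)


def _default_geometry(shape, patch_size, stride):
    if patch_size is None:
        patch_size = tuple(max(1, s // 4) for s in shape)
    elif np.isscalar(patch_size):
        patch_size = (int(patch_size),) * 3
    if stride is None:
        stride = tuple(max(1, p // 2) for p in patch_size)
    elif np.isscalar(stride):
        stride = (int(stride),) * 3
    return tuple(patch_size), tuple(stride)


def occlusion_map(model, volumes: np.ndarray, labels: np.ndarray,
                  patch_size=None, stride=None) -> OcclusionMap:
    """Accuracy decrease per zeroed input patch.

    ``model`` is anything with ``predict_proba(volumes) -> (n, 2)`` (or a
    callable returning class-1 probabilities).  Defaults: patch = 1/4 of
    each axis, stride = patch/2.  Deterministic given model and samples.
    """
    if len(volumes) == 0:
        raise ValueError("occlusion_map needs at least one sample")
    shape = volumes.shape[1:]
    patch_size, stride = _default_geometry(shape, patch_size, stride)

    def prob1(x):
        if hasattr(model, "predict_proba"):
            return np.asarray(model.predict_proba(x))[:, 1]
        return np.asarray(model(x))

    def acc(x):
        return float(((prob1(x) > 0.5).astype(int) == labels).mean())

    baseline = acc(volumes)
    starts = tuple(_axis_starts(s, p, st)
                   for s, p, st in zip(shape, patch_size, stride))
    drops = np.zeros(tuple(len(s) for s in starts))
    for iz, z0 in enumerate(starts[0]):
        for iy, y0 in enumerate(starts[1]):
            for ix, x0 in enumerate(starts[2]):
                occluded = volumes.copy()
                sl = (slice(None),) + tuple(
                    slice(s, s + p) for s, p in zip((z0, y0, x0), patch_size))
                occluded[sl] = 0.0
                drops[iz, iy, ix] = baseline - acc(occluded)
    return OcclusionMap(drops, starts, patch_size, stride, baseline)


def group_difference_map(values_by_group: dict[object, np.ndarray],
                         alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per ROI with BH-FDR correction.

    ``values_by_group`` maps exactly two group names to ``(n_subjects,
    n_roi)`` arrays.  Returns a DataFrame with columns ``roi, t, p, q,
    significant``; ROIs with zero variance in both groups get NaN statistics
    and ``significant=False``.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups are required")
    (ga, a), (gb, b) = values_by_group.items()
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the ROI dimension")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    t = np.full(a.shape[1], np.nan)
    p = np.full(a.shape[1], np.nan)
    valid = ~degenerate
    if valid.any():
        res = stats.ttest_ind(a[:, valid], b[:, valid], equal_var=False)
        t[valid], p[valid] = res.statistic, res.pvalue
    # identical groups give t == 0 exactly; keep p finite there
    q = np.full(a.shape[1], np.nan)
    sig = np.zeros(a.shape[1], dtype=bool)
    if valid.any():
        reject, qv, *_ = multipletests(p[valid], alpha=alpha_fdr,
                                       method="fdr_bh")
        q[valid], sig[valid] = qv, reject
    return pd.DataFrame({"roi": np.arange(a.shape[1]), "t": t, "p": p,
                         "q": q, "significant": sig,
                         "degenerate": degenerate})
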