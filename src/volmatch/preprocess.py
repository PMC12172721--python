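"""Gray-matter masking and per-image z-score normalization.

Each image is standardized inside the brain mask,

    x~_j = (x_j - mu) / sigma,

with ``mu`` and ``sigma`` the mean and (population) standard deviation of
the in-mask voxel values of that image; out-of-mask voxels are set to zero.
Centering forces every normalized image's voxel sum to zero, which removes
the voxel-sum channel that otherwise correlates strongly with total
intracranial volume — but not necessarily all TIV information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MaskSpec",
    "NormalizedImage",
    "binarize_mask",
    "zscore_normalize",
    "normalize_stack",
    "voxelsum_tiv_correlation",
]


@dataclass
class MaskSpec:
    """Binarized gray-matter mask derived from a probability grid."""

    prob_grid: np.ndarray
    threshold: float
    mask: np.ndarray  # boolean

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class NormalizedImage:
    """Z-score-normalized image with the statistics used."""

    values: np.ndarray
    mean: float
    sd: float
    mask: np.ndarray


def binarize_mask(prob_grid: np.ndarray, threshold: float = 0.5) -> MaskSpec:
    """Threshold a tissue-probability grid into a binary mask (inclusive >=)."""
    prob_grid = np.asarray(prob_grid, dtype=float)
    if prob_grid.min() < 0 or prob_grid.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    mask = prob_grid >= threshold
    if not mask.any():
        raise ValueError("binarized mask is empty")
    return MaskSpec(prob_grid=prob_grid, threshold=threshold, mask=mask)


def zscore_normalize(values: np.ndarray, mask: np.ndarray) -> NormalizedImage:
    """Standardize in-mask voxels to mean 0 / sd 1; zero outside the mask.

    Statistics are computed over in-mask voxels only, with the
    divide-by-N (population) standard deviation convention so that the
    operation is exactly idempotent.
    """
    values = np.asarray(values, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    inside = values[mask]
    mu = float(inside.mean())
    sigma = float(inside.std())  # ddof=0
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("constant in-mask image: sd is zero, cannot normalize")
    out = np.zeros_like(values)
    out[mask] = (inside - mu) / sigma
    return NormalizedImage(values=out, mean=mu, sd=sigma, mask=mask)


def normalize_stack(images: np.ndarray, mask: np.ndarray,
                    dtype=np.float32) -> np.ndarray:
    """Normalize a stack of images (n, nx, ny, nz) sharing one mask."""
    mask = np.asarray(mask, dtype=bool)
    flat = images.reshape(images.shape[0], -1)[:, mask.ravel()].astype(np.float64)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    if np.any(sd <= 1e-12 * np.maximum(1.0, np.abs(mu))):
        raise ValueError("constant in-mask image in stack")
    out = np.zeros(images.shape, dtype=dtype)
    out.reshape(images.shape[0], -1)[:, mask.ravel()] = (flat - mu) / sd
    return out


def voxelsum_tiv_correlation(
    images: np.ndarray,
    tiv_ml: np.ndarray,
    stage: str = "raw",
) -> dict:
    """Pearson correlation of per-subject voxel sum with TIV.

    After z-score normalization all voxel sums are (numerically) zero and
    the correlation is undefined; it is then reported as 0.0 with
    ``degenerate=True``.
    """
    if stage not in ("raw", "normalized"):
        raise ValueError("stage must be 'raw' or 'normalized'")
    tiv_ml = np.asarray(tiv_ml, dtype=float)
    if len(tiv_ml) < 3:
        raise ValueError("need n >= 3")
    sums = images.reshape(images.shape[0], -1).sum(axis=1).astype(np.float64)
    report = {"stage": stage, "n": len(tiv_ml), "degenerate": False}
    if np.ptp(tiv_ml) == 0:
        report.update(r=float("nan"), p=float("nan"), degenerate=True)
        return report
    # centering makes sums ~0 up to float accumulation error
    if np.allclose(sums, 0.0, atol=1e-3 * images[0].size ** 0.5) or np.ptp(sums) == 0:
        report.update(r=0.0, p=1.0, degenerate=True)
        return report
    r, p = stats.pearsonr(sums, tiv_ml)
    report.update(r=float(r), p=float(p))
    return report
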