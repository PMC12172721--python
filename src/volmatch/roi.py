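"""Region-of-interest importance: occlusion experiments and weight maps.

Two occlusion settings probe sufficiency and necessity of a region: 'only
ROI' keeps one region and zeroes everything else before training and
prediction; 'masked ROI' zeroes only that region.  Occlusion is applied to
the z-score-normalized images so the rest of the pipeline is unchanged.

For the linear model, voxel weights are made comparable across voxels by
scaling with the per-voxel standard deviation of the normalized values
over the training sample, ``w'_j = sigma_j * w_j``; sign-split sums of the
weight maps over the cross-validation repetitions give repeatability maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import ROIAtlas
from .cv import SplitPlan, run_nested_cv

__all__ = [
    "VoxelStats", "WeightMap", "AggregateMaps",
    "only_roi", "masked_roi", "roi_experiment",
    "voxel_stats", "normalize_weights", "aggregate_weight_maps",
]


def _check_roi(images: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != images.shape[-roi_mask.ndim:]:
        raise ValueError("ROI mask dimensions do not match images")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    return roi_mask


def only_roi(images: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Keep only the ROI voxels; all other voxels set to zero."""
    roi_mask = _check_roi(images, roi_mask)
    return images * roi_mask


def masked_roi(images: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Zero the ROI voxels; all other voxels unchanged."""
    roi_mask = _check_roi(images, roi_mask)
    return images * ~roi_mask


def roi_experiment(
    images: np.ndarray,
    labels: np.ndarray,
    ids,
    atlas: ROIAtlas,
    setting: str = "only",
    model_kinds: tuple[str, ...] = ("logreg",),
    scenario: str = "roi",
    *,
    seed: int = 0,
    k: int = 5,
    l: int = 5,
    epochs: int | None = None,
    regions: list[int] | None = None,
    include_whole_brain: bool = True,
    plan: SplitPlan | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Per-ROI nested-CV performance table under one occlusion setting.

    The same fold plan is reused for every region so rows are comparable.
    The table carries one row per region (plus a whole-brain row) and is
    sorted descending by the first model's AUC, ties broken by ROI voxel
    count descending.
    """
    if setting not in ("only", "masked"):
        raise ValueError("setting must be 'only' or 'masked'")
    occlude = only_roi if setting == "only" else masked_roi
    ids = list(ids)
    if plan is None:
        from .cv import make_nested_splits
        plan = make_nested_splits(ids, k=k, l=l, seed=seed)
    counts = atlas.region_voxel_counts()
    region_list = regions if regions is not None else sorted(counts)
    rows = []
    tasks = [(lab, atlas.region_mask(lab)) for lab in region_list]
    if include_whole_brain:
        tasks.append((None, atlas.mask))
    for lab, mask in tasks:
        # the whole-brain row is the unrestricted reference run
        imgs = images if lab is None else occlude(images, mask)
        row = {
            "roi": "whole_brain" if lab is None else atlas.label_table[lab],
            "setting": "whole" if lab is None else setting,
            "size_voxels": int(mask.sum()),
        }
        for kind in model_kinds:
            cvres = run_nested_cv(imgs, labels, ids, kind, scenario,
                                  seed=seed, plan=plan, epochs=epochs,
                                  keep_models=False, **cv_kwargs)
            row[f"auc_{kind}"] = cvres.mean_auc
            row[f"accuracy_{kind}"] = cvres.mean_accuracy
        rows.append(row)
    df = pd.DataFrame(rows)
    sort_col = f"auc_{model_kinds[0]}"
    return df.sort_values([sort_col, "size_voxels"],
                          ascending=[False, False]).reset_index(drop=True)


@dataclass
class VoxelStats:
    """Per-voxel standard deviation of normalized values over a sample."""

    sigma: np.ndarray


def voxel_stats(images: np.ndarray) -> VoxelStats:
    """Population per-voxel sd across the sample axis."""
    return VoxelStats(sigma=np.asarray(images, dtype=np.float64).std(axis=0))


@dataclass
class WeightMap:
    """Variance-normalized weight map ``w'_j = sigma_j * w_j``."""

    values: np.ndarray
    bias: float
    sigma: np.ndarray
    n_zero_sigma: int

    def reconstruct_score(self, image: np.ndarray) -> float:
        """Recompute the femaleness score from the normalized weights.

        Identity: ``z = w0 + sum_j w_j x~_j = w0 + sum_j w'_j x~_j / sigma_j``
        over voxels with ``sigma_j > 0`` (zero-sigma voxels are constant
        across the sample and carry no signal there).
        """
        ok = self.sigma > 0
        return float(self.bias
                     + np.sum(self.values[ok] * image[ok] / self.sigma[ok]))


def normalize_weights(results, stats: VoxelStats) -> WeightMap:
    """Scale a fitted linear model's voxel weights by the per-voxel sd."""
    w = results.weight_grid
    sigma = stats.sigma
    if w.shape != sigma.shape:
        raise ValueError("weight grid and voxel stats shape mismatch")
    zero = sigma == 0
    values = sigma * w
    values[zero] = 0.0
    return WeightMap(values=values, bias=results.bias, sigma=sigma,
                     n_zero_sigma=int(zero.sum()))


@dataclass
class AggregateMaps:
    """Sign-split repeatability maps over cross-validation repetitions."""

    positive: np.ndarray
    negative: np.ndarray
    positive_raw: np.ndarray  # voxelwise sums before smoothing/upsampling
    negative_raw: np.ndarray
    display_threshold: float
    out_voxel_mm: float


def aggregate_weight_maps(
    maps: list[np.ndarray],
    voxel_size_mm: float,
    *,
    fwhm_mm: float = 1.0,
    out_voxel_mm: float = 0.5,
    display_threshold: float = 7.0,
) -> AggregateMaps:
    """Combine weight maps from repeated trainings into two display maps.

    Each map is split by sign (negative values multiplied by -1), the
    splits are summed voxelwise across maps, smoothed with a Gaussian
    kernel of the given FWHM, interpolated into ``out_voxel_mm`` space,
    scaled to a maximum of 1 and multiplied by the number of maps.  The
    display threshold is only for rendering and is not applied here.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to aggregate")
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    pos_raw = np.clip(stack, 0.0, None).sum(axis=0)
    neg_raw = np.clip(-stack, 0.0, None).sum(axis=0)

    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    zoom = voxel_size_mm / out_voxel_mm

    def finish(raw):
        sm = ndimage.gaussian_filter(raw, sigma_vox, truncate=4.0)
        up = ndimage.zoom(sm, zoom, order=1)
        peak = up.max()
        if peak > 0:
            up = up / peak * len(maps)
        return up

    return AggregateMaps(positive=finish(pos_raw), negative=finish(neg_raw),
                         positive_raw=pos_raw, negative_raw=neg_raw,
                         display_threshold=display_threshold,
                         out_voxel_mm=out_voxel_mm)
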