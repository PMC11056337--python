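"""Atrophy-correction masking.

Cerebral atrophy widens CSF spaces (sulci, fissures, ventricles); after
smoothing, perfusion counts near those spaces drop for purely geometric
reasons and the voxel Z-scores are inflated.  The correction derives a
binary GM+WM brain mask from the subject's own T1 image — segment into
GM/WM/CSF, smooth each map with a 4-mm FWHM Gaussian, binarize, union GM
and WM — and removes everything outside it from the comparison domain of
both the subject and the control database.  Analyses run without / with
this mask are referred to as Mask(-) / Mask(+).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .template import NormalDatabase, smooth_gaussian
from .volume import ImageVolume

__all__ = [
    "TissueMaps",
    "BrainMask",
    "SegmentationError",
    "segment_t1",
    "make_brain_mask",
    "apply_mask_domain",
]


class SegmentationError(ValueError):
    pass


@dataclass
class TissueMaps:
    """Soft GM/WM/CSF membership maps on one grid (each in [0, 1], sum <= 1)."""

    gm: ImageVolume
    wm: ImageVolume
    csf: ImageVolume

    def __post_init__(self):
        grids = {self.gm.grid, self.wm.grid, self.csf.grid}
        if len(grids) != 1:
            raise ValueError("tissue maps must share one grid")
        total = (np.asarray(self.gm.values) + np.asarray(self.wm.values)
                 + np.asarray(self.csf.values))
        if np.nanmax(total) > 1 + 1e-6:
            raise ValueError("tissue memberships sum above 1")

    @property
    def grid(self):
        return self.gm.grid


@dataclass
class BrainMask:
    """Binary GM+WM mask; ``source`` records whether it came from a subject
    T1 segmentation or from phantom ground-truth tissue maps."""

    mask: ImageVolume
    source: str = "subject_t1"
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.source not in ("subject_t1", "phantom_truth"):
            raise ValueError(f"unknown mask source {self.source!r}")
        vals = np.asarray(self.mask.values)
        uniq = np.unique(vals[np.isfinite(vals)])
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary")
        if not vals.any():
            raise ValueError("mask is empty")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.mask.values) > 0.5

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())


def segment_t1(t1: ImageVolume, *, interior_frac: float = 0.2,
               random_state: int = 0) -> TissueMaps:
    """Three-class T1 segmentation by intensity clustering.

    Brain-interior voxels (intensity above ``interior_frac`` of the robust
    maximum) are clustered with k-means into three centres ordered
    CSF < GM < WM by T1 intensity.  Soft memberships are the normalized
    inverse squared distances to the centres; background voxels get zero
    membership in every class.
    """
    vals = np.asarray(t1.values, dtype=float)
    if vals.max() == vals.min():
        raise SegmentationError("T1 volume is constant; cannot segment")
    robust_max = np.percentile(vals, 99.5)
    interior = vals > interior_frac * robust_max
    x = vals[interior].reshape(-1, 1)
    if x.size < 3:
        raise SegmentationError("too few brain-interior voxels")
    km = KMeans(n_clusters=3, n_init=4, random_state=random_state)
    try:
        km.fit(x)
    except Exception as exc:
        raise SegmentationError(f"k-means failed: {exc}") from exc
    centers = np.sort(km.cluster_centers_.ravel())  # CSF < GM < WM
    if np.min(np.diff(centers)) < 1e-6 * max(1.0, abs(centers[-1])):
        raise SegmentationError("intensity distribution has fewer than 3 distinct clusters")

    d2 = (x - centers[None, :]) ** 2
    w = 1.0 / (d2 + 1e-12)
    w /= w.sum(axis=1, keepdims=True)
    maps = []
    for k in range(3):
        m = np.zeros_like(vals)
        m[interior] = w[:, k]
        maps.append(m)
    csf, gm, wm = maps
    return TissueMaps(
        gm=ImageVolume(t1.grid, gm, "probability"),
        wm=ImageVolume(t1.grid, wm, "probability"),
        csf=ImageVolume(t1.grid, csf, "probability"),
    )


def make_brain_mask(tissue: TissueMaps, smooth_fwhm_mm: float = 4.0,
                    binarize_threshold: float = 0.5,
                    source: str = "subject_t1") -> BrainMask:
    """GM+WM binary mask: smooth each soft map (4-mm FWHM), threshold, union.

    mask = [smooth(gm) >= t] OR [smooth(wm) >= t]
    """
    if not 0.0 < binarize_threshold < 1.0:
        raise ValueError(f"binarize threshold must be in (0, 1), got {binarize_threshold}")
    gm_s = smooth_gaussian(tissue.gm, smooth_fwhm_mm)
    wm_s = smooth_gaussian(tissue.wm, smooth_fwhm_mm)
    mask = ((np.asarray(gm_s.values) >= binarize_threshold)
            | (np.asarray(wm_s.values) >= binarize_threshold))
    return BrainMask(
        mask=ImageVolume(tissue.grid, mask.astype(np.float64), "probability"),
        source=source,
        binarize_threshold=binarize_threshold,
    )


def apply_mask_domain(subject: ImageVolume, db: NormalDatabase,
                      mask: BrainMask) -> tuple[ImageVolume, NormalDatabase]:
    """Remove extra-cerebral voxels from subject and database alike.

    Voxels outside the mask are set to NaN (undefined) in the subject volume
    and in the database mean/SD, so no downstream statistic can use them.
    Count normalization is NOT re-run here: masking only restricts the
    comparison domain.
    """
    if subject.grid != db.grid or mask.mask.grid != db.grid:
        raise ValueError("subject, database and mask must share one grid")
    keep = mask.array
    if not keep.any():
        raise ValueError("mask excludes every voxel")
    sub = np.asarray(subject.values, dtype=float).copy()
    sub[~keep] = np.nan
    mean = np.asarray(db.mean_vol.values, dtype=float).copy()
    sd = np.asarray(db.sd_vol.values, dtype=float).copy()
    mean[~keep] = np.nan
    sd[~keep] = np.nan
    masked_subject = ImageVolume(subject.grid, sub, subject.modality_tag, allow_nan=True)
    masked_db = NormalDatabase(
        mean_vol=ImageVolume(db.grid, mean, "SPECT", allow_nan=True),
        sd_vol=ImageVolume(db.grid, sd, "SPECT", allow_nan=True),
        n_subjects=db.n_subjects,
        smoothing_fwhm_mm=db.smoothing_fwhm_mm,
        normalization_tag=db.normalization_tag,
    )
    return masked_subject, masked_db
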