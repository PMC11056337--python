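"""Voxel-wise Z-score computation.

Z(v) = (mu_c(v) - s(v)) / sigma_c(v)

with mu_c/sigma_c the control mean/SD from the normal database and s the
subject's standardized, smoothed, global-mean-normalized count.  Positive Z
encodes hypoperfusion.  The comparison domain is the template's
35%-of-maximum count mask, intersected with the subject's GM+WM brain mask
for the Mask(+) (atrophy-corrected) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atrophy import BrainMask, apply_mask_domain
from .template import NormalDatabase
from .volume import ImageVolume

__all__ = [
    "ZScoreMap",
    "global_mean_normalize",
    "analysis_threshold_mask",
    "compute_zmap",
    "overestimation_image",
    "GLOBAL_MEAN_REFERENCE",
]

# Reference value the global mean is scaled to.  The Z statistic is invariant
# to this constant as long as subject and controls share it; 50 is the
# conventional pseudo-quantitative perfusion reference.
GLOBAL_MEAN_REFERENCE = 50.0

# Voxels whose control SD falls below this fraction of the reference are
# excluded from the analysis domain to avoid division blow-ups.
SIGMA_FLOOR_FRAC = 1e-3


@dataclass
class ZScoreMap:
    """Z volume plus the binary analysis domain it is defined on."""

    z: ImageVolume
    analysis_mask: ImageVolume
    masked_variant: bool
    db_n: int

    def __post_init__(self):
        if self.z.grid != self.analysis_mask.grid:
            raise ValueError("z and analysis mask must share a grid")
        inside = np.asarray(self.analysis_mask.values) > 0.5
        if not np.isfinite(np.asarray(self.z.values)[inside]).all():
            raise ValueError("Z values inside the analysis mask must be finite")

    @property
    def mask_array(self) -> np.ndarray:
        return np.asarray(self.analysis_mask.values) > 0.5

    @property
    def z_array(self) -> np.ndarray:
        return np.asarray(self.z.values)

    def values_in_mask(self) -> np.ndarray:
        return self.z_array[self.mask_array]


def global_mean_normalize(vol: ImageVolume, threshold_frac: float = 0.35,
                          reference: float = GLOBAL_MEAN_REFERENCE,
                          threshold_source: ImageVolume | None = None) -> ImageVolume:
    """Scale counts so the above-threshold global mean equals ``reference``.

    The global mean is taken over voxels at or above ``threshold_frac`` of
    the maximum count.  By default the threshold set comes from the volume
    itself; pass the symmetric template as ``threshold_source`` to use the
    template-derived analysis set instead (so Mask(-) and Mask(+) share one
    normalization).
    """
    if not 0.0 <= threshold_frac < 1.0:
        raise ValueError(f"threshold fraction must be in [0, 1), got {threshold_frac}")
    src = np.asarray((threshold_source or vol).values, dtype=float)
    vmax = np.nanmax(src)
    if not vmax > 0:
        raise ValueError("volume maximum must be positive")
    above = src >= threshold_frac * vmax
    if not above.any():
        raise ValueError("no voxels above the count threshold")
    vals = np.asarray(vol.values, dtype=float)
    gmean = float(vals[above].mean())
    if not gmean > 0:
        raise ValueError("global mean over the threshold set is not positive")
    return vol.with_values(vals * (reference / gmean))


def analysis_threshold_mask(template: ImageVolume,
                            threshold_frac: float = 0.35) -> np.ndarray:
    """Boolean analysis domain: voxels >= threshold_frac x template maximum."""
    vals = np.asarray(template.values, dtype=float)
    return vals >= threshold_frac * np.nanmax(vals)


def compute_zmap(subject: ImageVolume, db: NormalDatabase,
                 brain_mask: BrainMask | None = None,
                 template: ImageVolume | None = None,
                 threshold_frac: float = 0.35,
                 sigma_floor: float | None = None) -> ZScoreMap:
    """Voxel-wise Z = (mu_c - s)/sigma_c on the analysis domain.

    The domain is {template >= 35% max} (template defaults to the database
    mean) intersected with ``brain_mask`` when given (Mask(+)), minus voxels
    with near-zero control SD.  Z is NaN outside the domain.
    """
    if subject.grid != db.grid:
        raise ValueError("subject and database must share a grid")
    tmpl = template if template is not None else db.mean_vol
    if tmpl.grid != db.grid:
        raise ValueError("template and database must share a grid")
    if sigma_floor is None:
        sigma_floor = SIGMA_FLOOR_FRAC * GLOBAL_MEAN_REFERENCE

    if brain_mask is not None:
        subject, db = apply_mask_domain(subject, db, brain_mask)

    s = np.asarray(subject.values, dtype=float)
    mu = np.asarray(db.mean_vol.values, dtype=float)
    sigma = np.asarray(db.sd_vol.values, dtype=float)

    with np.errstate(invalid="ignore"):
        domain = analysis_threshold_mask(tmpl, threshold_frac)
        domain &= np.isfinite(s) & np.isfinite(mu) & np.isfinite(sigma)
        domain &= sigma >= sigma_floor
    if not domain.any():
        raise ValueError("empty analysis mask")

    z = np.full(s.shape, np.nan)
    z[domain] = (mu[domain] - s[domain]) / sigma[domain]
    return ZScoreMap(
        z=ImageVolume(subject.grid, z, "zmap"),
        analysis_mask=ImageVolume(subject.grid, domain.astype(np.float64), "probability"),
        masked_variant=brain_mask is not None,
        db_n=db.n_subjects,
    )


def overestimation_image(group_unmasked: list[ZScoreMap],
                         group_masked: list[ZScoreMap]) -> ImageVolume:
    """Group overestimation map: [mean + SD] Mask(-) minus [mean + SD] Mask(+).

    Defined on the intersection of the unmasked analysis masks.  Each term
    is computed per voxel over the subjects whose analysis domain contains
    that voxel; voxels the individual brain masks removed carry no Z on the
    masked side (their term is zero there), so atrophy-widened CSF spaces —
    present in the conventional analysis but eliminated by the masks — show
    up as positive overestimation.  The SD uses n-1 and is zero where fewer
    than two subjects cover the voxel.  NaN outside the common domain.
    """
    if len(group_unmasked) != len(group_masked):
        raise ValueError("paired groups must have the same length")
    if not group_unmasked:
        raise ValueError("empty group")
    grid = group_unmasked[0].z.grid
    for zm in list(group_unmasked) + list(group_masked):
        if zm.z.grid != grid:
            raise ValueError("all Z maps must share one grid")
    common = np.ones(grid.shape, dtype=bool)
    for zm in group_unmasked:
        common &= zm.mask_array
    if not common.any():
        raise ValueError("empty common analysis domain")

    def _mean_plus_sd(group: list[ZScoreMap]) -> np.ndarray:
        stack = np.stack([zm.z_array for zm in group])
        defined = np.stack([zm.mask_array for zm in group])
        count = defined.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(count >= 1,
                            np.nansum(np.where(defined, stack, 0.0), axis=0)
                            / np.maximum(count, 1), 0.0)
            sq = np.nansum(np.where(defined, (stack - mean) ** 2, 0.0), axis=0)
            sd = np.where(count >= 2, np.sqrt(sq / np.maximum(count - 1, 1)), 0.0)
        return np.where(count >= 1, mean + sd, 0.0)

    diff = _mean_plus_sd(group_unmasked) - _mean_plus_sd(group_masked)
    out = np.full(grid.shape, np.nan)
    out[common] = diff[common]
    return ImageVolume(grid, out, "zmap")
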