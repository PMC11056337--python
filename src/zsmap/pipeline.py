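"""High-level orchestration of the Z-score mapping analysis.

Ties the stages together the way a study runs them: build the symmetric
template and normal database from control SPECT scans; standardize, smooth
and count-normalize a subject scan; derive the subject's GM+WM mask; and
compute paired Mask(-)/Mask(+) Z maps with regional statistics and atrophy
correction rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atrophy import BrainMask, TissueMaps, make_brain_mask, segment_t1
from .config import RunConfig
from .phantom import Cohort
from .roi import (AtrophyCorrectionRecord, ROIAtlas, RegionStats, UndefinedRateError,
                  bilateral_average, regional_stats)
from .template import NormalDatabase, build_normal_db, build_symmetric_template, smooth_gaussian
from .volume import ImageVolume
from .zscore import ZScoreMap, compute_zmap, global_mean_normalize

__all__ = [
    "build_template_and_db",
    "prepare_subject",
    "SubjectAnalysis",
    "analyze_subject",
    "run_phantom_study",
    "PHANTOM_STUDY_CONFIG",
]

# Phantom renders already carry the full effective resolution through their
# system PSF, so phantom studies skip the reconstruction-smoothing step that
# real acquisitions need; applying it on top would double-count resolution
# and leave only long-range inter-subject variance in the normal database.
PHANTOM_STUDY_CONFIG = RunConfig(spect_fwhm_mm=0.0)


def build_template_and_db(control_spects: list[ImageVolume],
                          config: RunConfig = RunConfig(),
                          ) -> tuple[ImageVolume, NormalDatabase]:
    """Symmetric template and normal database from standardized control scans.

    Each control scan is smoothed (12-mm FWHM), count-normalized on its own
    35% threshold set, averaged and left-right folded into the symmetric
    template; the controls are then re-normalized against the template's
    threshold set and reduced to per-voxel mean/SD.
    """
    smoothed = [smooth_gaussian(v, config.spect_fwhm_mm) for v in control_spects]
    self_norm = [global_mean_normalize(v, config.analysis_threshold_frac,
                                       config.global_mean_reference) for v in smoothed]
    template = build_symmetric_template(self_norm)
    normalized = [global_mean_normalize(v, config.analysis_threshold_frac,
                                        config.global_mean_reference,
                                        threshold_source=template) for v in smoothed]
    db = build_normal_db(normalized, smoothing_fwhm_mm=config.spect_fwhm_mm,
                         normalization_tag=f"global-mean-{config.global_mean_reference:g}")
    return template, db


def prepare_subject(spect: ImageVolume, template: ImageVolume,
                    config: RunConfig = RunConfig()) -> ImageVolume:
    """Smooth and count-normalize a standardized subject scan.

    The global mean is computed over the template's 35% threshold set, so
    the Mask(-) and Mask(+) analyses share one normalization and masking
    only restricts the comparison domain.
    """
    smoothed = smooth_gaussian(spect, config.spect_fwhm_mm)
    return global_mean_normalize(smoothed, config.analysis_threshold_frac,
                                 config.global_mean_reference, threshold_source=template)


@dataclass
class SubjectAnalysis:
    """Paired Mask(-)/Mask(+) results for one subject."""

    zmap_unmasked: ZScoreMap
    zmap_masked: ZScoreMap
    brain_mask: BrainMask
    stats_unmasked: list[RegionStats] = field(default_factory=list)
    stats_masked: list[RegionStats] = field(default_factory=list)
    records: list[AtrophyCorrectionRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-region table: one row per region x mask state."""
        rows = []
        rate_by_region = {r.region: r.rate_pct for r in self.records}
        for masked, stats in ((False, self.stats_unmasked), (True, self.stats_masked)):
            for s in stats:
                rows.append({
                    "region": s.region, "side": s.side, "masked": masked,
                    "mean_z": s.mean_z, "extent_pct": s.extent_pct,
                    "n_voxels": s.n_voxels,
                    "rate_pct": rate_by_region.get(s.region, np.nan),
                })
        return pd.DataFrame(rows)


def analyze_subject(spect: ImageVolume, db: NormalDatabase, template: ImageVolume,
                    atlas: ROIAtlas | None = None,
                    t1: ImageVolume | None = None,
                    truth_tissue: TissueMaps | None = None,
                    config: RunConfig = RunConfig()) -> SubjectAnalysis:
    """Full paired analysis of one subject.

    The GM+WM mask comes from ``truth_tissue`` when given (phantom
    ground-truth mode, isolating the masking logic from segmentation error)
    and otherwise from segmenting ``t1``.  With an atlas, bilateral regional
    statistics and per-region atrophy correction rates are attached.
    """
    if truth_tissue is not None:
        tissue = truth_tissue
        source = "phantom_truth"
    elif t1 is not None:
        tissue = segment_t1(t1)
        source = "subject_t1"
    else:
        raise ValueError("need either a T1 volume or ground-truth tissue maps")
    mask = make_brain_mask(tissue, config.mask_fwhm_mm, config.mask_binarize_threshold,
                           source=source)

    subject = prepare_subject(spect, template, config)
    z_unmasked = compute_zmap(subject, db, brain_mask=None, template=template,
                              threshold_frac=config.analysis_threshold_frac,
                              sigma_floor=config.sigma_floor)
    subject_masked = subject
    if config.renormalize_in_mask:
        subject_masked = global_mean_normalize(
            smooth_gaussian(spect, config.spect_fwhm_mm),
            config.analysis_threshold_frac, config.global_mean_reference,
            threshold_source=template.with_values(
                np.where(mask.array, np.asarray(template.values), 0.0)))
    z_masked = compute_zmap(subject_masked, db, brain_mask=mask, template=template,
                            threshold_frac=config.analysis_threshold_frac,
                            sigma_floor=config.sigma_floor)

    analysis = SubjectAnalysis(zmap_unmasked=z_unmasked, zmap_masked=z_masked, brain_mask=mask)
    if atlas is not None:
        analysis.stats_unmasked = bilateral_average(
            regional_stats(z_unmasked, atlas, config.z_extent))
        analysis.stats_masked = bilateral_average(
            regional_stats(z_masked, atlas, config.z_extent))
        masked_by_region = {s.region: s for s in analysis.stats_masked}
        for s in analysis.stats_unmasked:
            m = masked_by_region.get(s.region)
            if m is None:
                continue
            try:
                analysis.records.append(
                    AtrophyCorrectionRecord.from_pair(s.region, s.mean_z, m.mean_z))
            except UndefinedRateError:
                continue
        analysis.stats_unmasked = [s for s in analysis.stats_unmasked]
    return analysis


def run_phantom_study(cohort: Cohort, config: RunConfig = PHANTOM_STUDY_CONFIG,
                      use_truth_tissue: bool = True) -> pd.DataFrame:
    """Analyze a phantom cohort end to end.

    Builds the template and normal database from the cohort's controls and
    analyzes every patient against them.  Returns a tidy frame with one row
    per patient x region x mask state (columns ``subject``, ``region``,
    ``side``, ``masked``, ``mean_z``, ``extent_pct``, ``n_voxels``,
    ``rate_pct``).  The default config disables the acquisition-smoothing
    step (see ``PHANTOM_STUDY_CONFIG``); pass an explicit config to override.
    """
    template, db = build_template_and_db([s.spect for s in cohort.controls], config)
    frames = []
    for i, subj in enumerate(cohort.patients):
        analysis = analyze_subject(
            subj.spect, db, template, atlas=cohort.atlas,
            t1=None if use_truth_tissue else subj.t1,
            truth_tissue=subj.truth_tissue if use_truth_tissue else None,
            config=config)
        frame = analysis.to_frame()
        frame.insert(0, "subject", f"patient_{i:03d}")
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
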