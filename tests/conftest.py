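"""Shared fixtures and helpers for the zsmap test suite."""

import numpy as np
import pytest

import zsmap as z
from zsmap.volume import ImageVolume, VolumeGrid


def make_grid(shape=(8, 8, 8), voxel=2.0):
    return VolumeGrid(tuple(shape), (voxel,) * 3)


def uniform_volume(value=1.0, shape=(8, 8, 8), voxel=2.0, tag="SPECT"):
    grid = make_grid(shape, voxel)
    return ImageVolume(grid, np.full(grid.shape, float(value)), tag)


def random_volume(rng, shape=(8, 8, 8), voxel=2.0, tag="SPECT", lo=10.0, hi=100.0):
    grid = make_grid(shape, voxel)
    return ImageVolume(grid, rng.uniform(lo, hi, grid.shape), tag)


@pytest.fixture(scope="session")
def atrophy_study():
    """Seeded atrophy-only cohort (15 controls a=0.05, 10 patients a=0.5, no
    lesions) with template, database and full per-patient paired analyses.

    Shared by the direction-of-effect acceptance test and the module-level
    masking tests; every consumer reads, never mutates.
    """
    control = z.PhantomSpec(atrophy_severity=0.05, seed=0)
    patient = z.PhantomSpec(atrophy_severity=0.5, seed=0)
    cohort = z.make_cohort(15, 10, control, patient, seed=5)
    template, db = z.build_template_and_db(
        [s.spect for s in cohort.controls], z.PHANTOM_STUDY_CONFIG)
    analyses = [
        z.analyze_subject(s.spect, db, template, atlas=cohort.atlas,
                          truth_tissue=s.truth_tissue, config=z.PHANTOM_STUDY_CONFIG)
        for s in cohort.patients
    ]
    frames = []
    for i, a in enumerate(analyses):
        frame = a.to_frame()
        frame.insert(0, "subject", f"patient_{i:03d}")
        frames.append(frame)
    import pandas as pd

    df = pd.concat(frames, ignore_index=True)
    return {"cohort": cohort, "template": template, "db": db,
            "analyses": analyses, "df": df}


@pytest.fixture(scope="session")
def clean_cohort_study():
    """Low-noise cohort with controls and patients from one distribution at
    zero extra atrophy spread: the regime where Mask(-) and Mask(+) must
    agree for interior ROIs."""
    spec = z.PhantomSpec(atrophy_severity=0.05, atrophy_jitter=0.0, noise_cv=0.02,
                         biological_cv=0.0, amplitude_jitter=0.0, t1_noise_sd=0.0,
                         seed=0)
    cohort = z.make_cohort(15, 3, spec, spec, seed=4)
    df = z.run_phantom_study(cohort)
    return {"cohort": cohort, "df": df}
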