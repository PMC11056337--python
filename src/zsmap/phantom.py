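"""Synthetic brain phantoms: paired T1/SPECT cohorts with known truth.

The generator emulates the data regime the pipeline is built for: an
ellipsoidal brain with a cortical grey-matter ribbon, a white-matter core,
ventricles and radial sulcal clefts.  One ``atrophy_severity`` parameter in
[0, 1] widens the sulci, the interhemispheric fissure and the subarachnoid
CSF layer and enlarges the ventricles, all at grey matter's expense, so
grey-matter volume decreases strictly with severity.  SPECT is rendered as
tissue-weighted activity (GM:WM uptake ratio 4:1 by default, mimicking
ECD-like perfusion contrast), degraded by an 8-mm FWHM system PSF and
multiplicative Gaussian noise; T1 is a three-level tissue contrast with
additive noise.  Focal hypoperfusion lesions of known fractional depth can
be planted in named atlas regions.

All tissue fields are smooth (half-voxel soft edges), so phantom series are
well behaved under small parameter changes.  Everything derives
deterministically from one master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .atrophy import TissueMaps
from .roi import ROIAtlas, DEMENTIA_REGIONS
from .template import FWHM_TO_SIGMA
from .volume import ImageVolume, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "Cohort",
    "make_anatomy",
    "render_t1",
    "render_spect",
    "make_subject",
    "make_cohort",
]

# Brain geometry (mm, semi-axes from the grid centre) and tissue contrast.
BRAIN_SEMI_AXES = (66.0, 80.0, 62.0)      # left-right, post-ant, inf-sup
WM_CORE_FRACTION = 0.62                   # WM core semi-axes as fraction of brain
VENTRICLE_CENTERS = ((-13.0, 5.0, -5.0), (13.0, 5.0, -5.0))
VENTRICLE_SEMI_AXES = (7.0, 20.0, 9.0)
VENTRICLE_ATROPHY_GAIN = 0.5              # semi-axis scale = 1 + gain * severity
N_SULCI = 10
SULCUS_BASE_WIDTH_MM = 1.5
SULCUS_ATROPHY_WIDTH_MM = 4.0             # width = base + gain * severity
FISSURE_BASE_WIDTH_MM = 1.0
FISSURE_ATROPHY_WIDTH_MM = 4.0
OUTER_CSF_BASE_FRAC = 0.03                # subarachnoid layer, fraction of radius
OUTER_CSF_ATROPHY_FRAC = 0.04
SULCUS_INNER_RADIUS = 0.60                # clefts only cut the outer shell
T1_CONTRAST = {"csf": 1.0, "gm": 2.5, "wm": 3.5}
MEDIAL_HALF_WIDTH_MM = 18.0               # |x| below this = medial cortex

# sector index (45-deg wedges around the left-right axis, from anterior up
# over the vertex to posterior and under) -> (lateral name, medial name)
SECTOR_REGIONS = (
    ("inferior_frontal", "medial_frontal"),
    ("middle_frontal", "superior_frontal"),
    ("postcentral", "paracentral"),
    ("superior_parietal", "precuneus"),
    ("angular", "posterior_cingulate"),
    ("supramarginal", "lingual"),
    ("inferior_temporal", "parahippocampal"),
    ("middle_temporal", "orbitofrontal"),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one subject (or a cohort's base subject)."""

    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid((64, 64, 64), (3.0, 3.0, 3.0)))
    atrophy_severity: float = 0.05
    atrophy_jitter: float = 0.02
    lesions: tuple[tuple[str, float], ...] = ()
    gm_wm_activity_ratio: float = 4.0
    psf_fwhm_mm: float = 8.0
    noise_cv: float = 0.05
    biological_cv: float = 0.10
    biological_fwhm_mm: float = 8.0
    t1_noise_sd: float = 0.05
    amplitude_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.atrophy_severity <= 1.0:
            raise ValueError("atrophy_severity must be in [0, 1]")
        for name, d in self.lesions:
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"lesion depth for {name!r} must be in [0, 1]")
        if min(self.grid.shape) < 32:
            raise ValueError("phantom grid must be at least 32 voxels per axis")
        if self.gm_wm_activity_ratio <= 0 or self.psf_fwhm_mm < 0:
            raise ValueError("activity ratio must be positive and PSF non-negative")
        if self.noise_cv < 0 or self.t1_noise_sd < 0 or self.biological_cv < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class PhantomSubject:
    t1: ImageVolume
    spect: ImageVolume
    truth_tissue: TissueMaps
    atlas: ROIAtlas
    truth_lesions: tuple[tuple[str, float], ...]
    spec: PhantomSpec


@dataclass
class Cohort:
    controls: list[PhantomSubject]
    patients: list[PhantomSubject]
    atlas: ROIAtlas
    manifest: dict


# ---------------------------------------------------------------------------
# geometry helpers

def _soft_below(x: np.ndarray, threshold: float, eps: float) -> np.ndarray:
    """Smooth indicator of x < threshold with a linear edge of width eps."""
    return np.clip((threshold - x) / eps + 0.5, 0.0, 1.0)


def _offsets_mm(grid: VolumeGrid):
    cx, cy, cz = grid.center_mm
    xs, ys, zs = grid.world_coords()
    x = (xs - cx)[:, None, None]
    y = (ys - cy)[None, :, None]
    z = (zs - cz)[None, None, :]
    return x, y, z


def _ellipsoid_radius(x, y, z, semi_axes) -> np.ndarray:
    ax, ay, az = semi_axes
    return np.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)


def make_anatomy(spec: PhantomSpec, atlas: ROIAtlas | None = None,
                 ) -> tuple[TissueMaps, ROIAtlas]:
    """Construct soft GM/WM/CSF maps and the sector atlas for one subject.

    Atrophy widens sulcal/ventricular/subarachnoid CSF at grey matter's
    expense.  The atlas is defined on the severity-zero geometry (a fixed
    stereotactic parcellation shared by every subject on the same grid);
    pass a prebuilt one to skip recomputation.
    """
    grid = spec.grid
    a = spec.atrophy_severity
    x, y, z = _offsets_mm(grid)
    vox = float(np.mean(grid.voxel_size))
    eps_mm = 0.5 * vox
    eps_r = eps_mm / float(np.mean(BRAIN_SEMI_AXES))

    r_brain = _ellipsoid_radius(x, y, z, BRAIN_SEMI_AXES)
    brain = _soft_below(r_brain, 1.0, eps_r)

    wm_axes = tuple(s * WM_CORE_FRACTION for s in BRAIN_SEMI_AXES)
    r_wm = _ellipsoid_radius(x, y, z, wm_axes)
    wm_core = _soft_below(r_wm, 1.0, eps_r / WM_CORE_FRACTION)

    # CSF components (fractions of the intracranial volume)
    outer_frac = OUTER_CSF_BASE_FRAC + OUTER_CSF_ATROPHY_FRAC * a
    outer_csf = 1.0 - _soft_below(r_brain, 1.0 - outer_frac, eps_r)

    vent_scale = 1.0 + VENTRICLE_ATROPHY_GAIN * a
    vent_axes = tuple(s * vent_scale for s in VENTRICLE_SEMI_AXES)
    ventricles = np.zeros_like(r_brain)
    for cx0, cy0, cz0 in VENTRICLE_CENTERS:
        rv = _ellipsoid_radius(x - cx0, y - cy0, z - cz0, vent_axes)
        v = _soft_below(rv, 1.0, eps_mm / float(np.mean(vent_axes)))
        ventricles = 1.0 - (1.0 - ventricles) * (1.0 - v)

    # radial sulcal clefts in the outer shell, wedges around the L-R axis
    shell = 1.0 - _soft_below(r_brain, SULCUS_INNER_RADIUS, eps_r)
    r_yz = np.sqrt(y ** 2 + z ** 2) + 1e-9
    phi = np.arctan2(z, y)  # 0 = anterior, +pi/2 = superior
    width = SULCUS_BASE_WIDTH_MM + SULCUS_ATROPHY_WIDTH_MM * a
    sulci = np.zeros_like(r_brain)
    angles = (np.arange(N_SULCI) + 0.5) * (2.0 * np.pi / N_SULCI)
    for theta in angles:
        dphi = np.angle(np.exp(1j * (phi - theta)))
        arc_mm = np.abs(dphi) * r_yz
        s = _soft_below(arc_mm, width / 2.0, eps_mm) * shell
        sulci = 1.0 - (1.0 - sulci) * (1.0 - s)
    fiss_width = FISSURE_BASE_WIDTH_MM + FISSURE_ATROPHY_WIDTH_MM * a
    fissure = _soft_below(np.abs(x) * np.ones_like(r_brain), fiss_width / 2.0, eps_mm) * shell
    sulci = 1.0 - (1.0 - sulci) * (1.0 - fissure)

    csf_frac = np.clip(outer_csf + ventricles + sulci, 0.0, 1.0)
    parenchyma = brain * (1.0 - csf_frac)
    wm = parenchyma * wm_core
    gm = parenchyma * (1.0 - wm_core)
    csf = brain * csf_frac

    tissue = TissueMaps(
        gm=ImageVolume(grid, gm, "probability"),
        wm=ImageVolume(grid, wm, "probability"),
        csf=ImageVolume(grid, csf, "probability"),
    )
    if atlas is None:
        atlas = _build_atlas(grid)
    return tissue, atlas


def _build_atlas(grid: VolumeGrid) -> ROIAtlas:
    """Fixed bilateral sector parcellation on the severity-zero geometry."""
    x, y, z = _offsets_mm(grid)
    r_brain = _ellipsoid_radius(x, y, z, BRAIN_SEMI_AXES)
    wm_axes = tuple(s * WM_CORE_FRACTION for s in BRAIN_SEMI_AXES)
    r_wm = _ellipsoid_radius(x, y, z, wm_axes)
    brain = r_brain <= 1.0
    wm_core = r_wm <= 1.0

    # baseline ventricles stay unlabeled
    vent = np.zeros(grid.shape, dtype=bool)
    for cx0, cy0, cz0 in VENTRICLE_CENTERS:
        rv = _ellipsoid_radius(x - cx0, y - cy0, z - cz0, VENTRICLE_SEMI_AXES)
        vent |= rv <= 1.0

    cortical = brain & ~wm_core & ~vent
    deep = brain & wm_core & ~vent

    phi = np.arctan2(z, y) * np.ones_like(r_brain)
    sector = np.floor(((np.degrees(phi) + 22.5) % 360.0) / 45.0).astype(int)
    medial = (np.abs(x) < MEDIAL_HALF_WIDTH_MM) * np.ones(grid.shape, dtype=bool)
    left = (x < 0) * np.ones(grid.shape, dtype=bool)

    labels = np.zeros(grid.shape, dtype=np.int32)
    rows = []
    names: list[str] = []
    for lat_name, med_name in SECTOR_REGIONS:
        names.extend([lat_name, med_name])
    names.append("white_matter")

    for i, name in enumerate(names):
        lab_l, lab_r = 2 * i + 1, 2 * i + 2
        for lab, hemi in ((lab_l, "L"), (lab_r, "R")):
            rows.append({
                "label": lab, "name": name, "hemisphere": hemi,
                "partner_label": lab_r if hemi == "L" else lab_l,
                "dementia_related": name in DEMENTIA_REGIONS,
            })
    name_index = {name: i for i, name in enumerate(names)}

    for s, (lat_name, med_name) in enumerate(SECTOR_REGIONS):
        in_sector = cortical & (sector == s)
        for name, zone in ((lat_name, in_sector & ~medial), (med_name, in_sector & medial)):
            i = name_index[name]
            labels[zone & left] = 2 * i + 1
            labels[zone & ~left] = 2 * i + 2
    i = name_index["white_matter"]
    labels[deep & left] = 2 * i + 1
    labels[deep & ~left] = 2 * i + 2

    regions = pd.DataFrame(rows)
    return ROIAtlas(labels=ImageVolume(grid, labels, "label"), regions=regions)


# ---------------------------------------------------------------------------
# rendering

def render_t1(tissue: TissueMaps, spec: PhantomSpec,
              rng: np.random.Generator | None = None) -> ImageVolume:
    """T1-like contrast: 1.0 CSF + 2.5 GM + 3.5 WM plus Gaussian noise >= 0."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    vals = (T1_CONTRAST["csf"] * np.asarray(tissue.csf.values)
            + T1_CONTRAST["gm"] * np.asarray(tissue.gm.values)
            + T1_CONTRAST["wm"] * np.asarray(tissue.wm.values))
    if spec.t1_noise_sd > 0:
        vals = vals + rng.normal(0.0, spec.t1_noise_sd, vals.shape)
    return ImageVolume(tissue.grid, np.clip(vals, 0.0, None), "T1")


def render_spect(tissue: TissueMaps, atlas: ROIAtlas, spec: PhantomSpec,
                 rng: np.random.Generator | None = None,
                 add_noise: bool = True) -> ImageVolume:
    """Perfusion activity: GM x ratio + WM, lesioned, PSF-blurred, noisy.

    Activity is scaled by (1 - depth) inside each lesioned region (both
    hemispheres of the named region) and modulated by a smooth per-subject
    biological variability field (multiplicative, ``biological_cv`` relative
    SD with ``biological_fwhm_mm`` spatial correlation — the inter-subject
    perfusion variation a normal database really contains).  The result is
    convolved with the isotropic system PSF and finally multiplied by
    1 + CV x N(0, 1) measurement noise, clipped at zero.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    activity = (spec.gm_wm_activity_ratio * np.asarray(tissue.gm.values)
                + np.asarray(tissue.wm.values))
    labels = np.asarray(atlas.labels.values)
    for name, depth in spec.lesions:
        region_labels = atlas.labels_for_name(name)  # KeyError on unknown region
        lesion_mask = np.isin(labels, region_labels)
        activity = np.where(lesion_mask, activity * (1.0 - depth), activity)
    if spec.biological_cv > 0:
        sigma_vox = [spec.biological_fwhm_mm * FWHM_TO_SIGMA / v
                     for v in tissue.grid.voxel_size]
        field = ndimage.gaussian_filter(rng.standard_normal(activity.shape),
                                        sigma=sigma_vox, mode="wrap")
        field /= field.std()
        activity = activity * np.clip(1.0 + spec.biological_cv * field, 0.05, None)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / v for v in tissue.grid.voxel_size]
        activity = ndimage.gaussian_filter(activity, sigma=sigma_vox, mode="constant")
    if add_noise and spec.noise_cv > 0:
        activity = activity * (1.0 + rng.normal(0.0, spec.noise_cv, activity.shape))
    return ImageVolume(tissue.grid, np.clip(activity, 0.0, None), "SPECT")


def make_subject(spec: PhantomSpec, atlas: ROIAtlas | None = None) -> PhantomSubject:
    """Generate one phantom subject (anatomy, T1, SPECT) from its spec."""
    rng = np.random.default_rng(spec.seed)
    tissue, atlas = make_anatomy(spec, atlas=atlas)
    t1 = render_t1(tissue, spec, rng=rng)
    spect = render_spect(tissue, atlas, spec, rng=rng)
    if spec.amplitude_jitter > 0:
        factor = float(np.exp(rng.normal(0.0, spec.amplitude_jitter)))
        spect = spect.with_values(np.asarray(spect.values) * factor)
    return PhantomSubject(t1=t1, spect=spect, truth_tissue=tissue, atlas=atlas,
                          truth_lesions=spec.lesions, spec=spec)


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def make_cohort(n_controls: int, n_patients: int,
                control_spec: PhantomSpec, patient_spec: PhantomSpec,
                seed: int = 0) -> Cohort:
    """Seeded cohort of independent control and patient subjects.

    Per-subject atrophy severity is drawn around the group spec's value
    (Gaussian with the spec's jitter, clipped to [0, 0.95]); every subject
    gets its own derived seed, recorded in the manifest, so the same master
    seed reproduces the cohort bitwise.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls for a normal database")
    seeds = _derive_seeds(seed, n_controls + n_patients)
    atlas = _build_atlas(control_spec.grid)

    def _vary(base: PhantomSpec, subject_seed: int) -> PhantomSpec:
        rng = np.random.default_rng(subject_seed)
        a = float(np.clip(rng.normal(base.atrophy_severity, base.atrophy_jitter), 0.0, 0.95))
        return dataclasses.replace(base, atrophy_severity=a, seed=subject_seed)

    controls, patients = [], []
    for i in range(n_controls):
        controls.append(make_subject(_vary(control_spec, seeds[i]), atlas=atlas))
    for j in range(n_patients):
        patients.append(make_subject(_vary(patient_spec, seeds[n_controls + j]), atlas=atlas))

    manifest = {
        "master_seed": int(seed),
        "n_controls": n_controls,
        "n_patients": n_patients,
        "control_spec": _spec_dict(control_spec),
        "patient_spec": _spec_dict(patient_spec),
        "subject_seeds": seeds,
        "subject_atrophy": [s.spec.atrophy_severity for s in controls + patients],
    }
    return Cohort(controls=controls, patients=patients, atlas=atlas, manifest=manifest)


def _spec_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["grid"] = {"shape": list(spec.grid.shape), "voxel_size": list(spec.grid.voxel_size),
                 "origin": list(spec.grid.origin)}
    d["lesions"] = [list(l) for l in spec.lesions]
    return d
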