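"""Symmetric perfusion template, spatial standardization, normal database.

The control-side statistics of the Z equation live here: a symmetric mean
SPECT template (left folded onto right, so left-right asymmetries in a
patient stand out against it) and a per-voxel normal database holding the
control mean and standard deviation after spatial standardization, 12-mm
smoothing and global-mean count normalization.

Spatial standardization is affine (translation, rotation, scale, shear),
estimated by multi-resolution least-squares intensity matching.  Nonlinear
warping is deliberately out of scope: phantom subjects are generated
pre-aligned up to affine perturbations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import ImageVolume, VolumeGrid, flip_left_right, common_grid, read_volume, write_volume

__all__ = [
    "AffineTransform",
    "NormalDatabase",
    "RegistrationWarning",
    "smooth_gaussian",
    "register_affine",
    "build_symmetric_template",
    "build_normal_db",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM / 2.3548


class RegistrationWarning(UserWarning):
    pass


def smooth_gaussian(vol: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Isotropic Gaussian smoothing specified by FWHM in mm.

    sigma_mm = fwhm / (2 sqrt(2 ln 2)) is converted to voxel units per axis.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"FWHM must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in vol.grid.voxel_size]
    out = ndimage.gaussian_filter(np.asarray(vol.values, dtype=float), sigma=sigma_vox,
                                  mode="constant", cval=0.0)
    return vol.with_values(out)


# ---------------------------------------------------------------------------
# Affine transform surface

@dataclass(frozen=True)
class AffineTransform:
    """12-parameter affine: translation (mm), rotation (deg), scale, shear.

    Maps world coordinates as x -> A (x - c) + c + t about a fixed centre
    ``c`` with linear part A = Rz Ry Rx . Shear . Scale.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scales must be positive, got {self.scale}")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(center=tuple(float(c) for c in center))

    @property
    def matrix(self) -> np.ndarray:
        """Linear part A (3x3)."""
        rx, ry, rz = (math.radians(a) for a in self.rotation_deg)
        Rx = np.array([[1, 0, 0], [0, math.cos(rx), -math.sin(rx)], [0, math.sin(rx), math.cos(rx)]])
        Ry = np.array([[math.cos(ry), 0, math.sin(ry)], [0, 1, 0], [-math.sin(ry), 0, math.cos(ry)]])
        Rz = np.array([[math.cos(rz), -math.sin(rz), 0], [math.sin(rz), math.cos(rz), 0], [0, 0, 1]])
        Sh = np.eye(3)
        Sh[0, 1], Sh[0, 2], Sh[1, 2] = self.shear
        S = np.diag(self.scale)
        return Rz @ Ry @ Rx @ Sh @ S

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        c = np.asarray(self.center)
        return (self.matrix @ (xyz - c).T).T + c + np.asarray(self.translation)

    @classmethod
    def from_matrix(cls, A: np.ndarray, translation, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        """Decompose linear part A into rotation/shear/scale (RQ-style)."""
        A = np.asarray(A, dtype=float)
        # polar-free decomposition: A = R U with R rotation via Gram-Schmidt on columns
        # Use QR of A: A = Q Rup ; enforce positive diagonal of Rup.
        Q, Rup = np.linalg.qr(A)
        signs = np.sign(np.diag(Rup))
        signs[signs == 0] = 1.0
        Q = Q * signs
        Rup = (Rup.T * signs).T
        if np.linalg.det(Q) < 0:  # proper rotation required
            Q[:, -1] *= -1
            Rup[-1, :] *= -1
        scale = np.diag(Rup).copy()
        Sh = Rup / scale[:, None]
        shear = (Sh[0, 1], Sh[0, 2], Sh[1, 2])
        # Euler angles from Q = Rz Ry Rx
        ry = math.asin(max(-1.0, min(1.0, -Q[2, 0])))
        if abs(math.cos(ry)) > 1e-8:
            rx = math.atan2(Q[2, 1], Q[2, 2])
            rz = math.atan2(Q[1, 0], Q[0, 0])
        else:  # gimbal lock, put everything in rz
            rx = 0.0
            rz = math.atan2(-Q[0, 1], Q[1, 1])
        return cls(
            translation=tuple(float(t) for t in np.asarray(translation)),
            rotation_deg=(math.degrees(rx), math.degrees(ry), math.degrees(rz)),
            scale=tuple(float(s) for s in scale),
            shear=tuple(float(s) for s in shear),
            center=tuple(float(c) for c in center),
        )


# ---------------------------------------------------------------------------
# Registration (SimpleITK backend)

def _to_sitk(vol: ImageVolume) -> sitk.Image:
    # sitk expects (z, y, x) array order
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(vol.values, dtype=np.float64).transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(v) for v in vol.grid.voxel_size))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin))
    return img


def _from_sitk(img: sitk.Image, grid: VolumeGrid, tag: str) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(grid, np.clip(arr, 0, None) if tag == "SPECT" else arr, tag)


def _mean_match(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Scale factor aligning global means of the two intensity distributions."""
    m, f = float(np.mean(moving)), float(np.mean(fixed))
    if m <= 0:
        return 1.0
    return f / m


def register_affine(moving: ImageVolume, fixed: ImageVolume, *,
                    do_affine_refine: bool = True,
                    ) -> tuple[AffineTransform, ImageVolume]:
    """Estimate the affine transform mapping ``moving`` onto ``fixed``.

    Least-squares intensity matching after global-mean intensity scaling,
    optimized multi-resolution (3-level pyramid) from the identity: a rigid
    stage followed by an optional full-affine refinement.  Returns the
    transform and the moving volume resampled into the fixed grid.  If the
    optimizer fails to improve on the identity a warning is emitted and the
    identity transform is returned.
    """
    for name, v in (("moving", moving), ("fixed", fixed)):
        vals = np.asarray(v.values, dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"{name} volume must be finite")
        if vals.max() == vals.min():
            raise ValueError(f"{name} volume is constant; registration undefined")

    scale = _mean_match(np.asarray(moving.values), np.asarray(fixed.values))
    mov_img = _to_sitk(moving.with_values(np.asarray(moving.values) * scale))
    fix_img = _to_sitk(fixed)

    def _metric(tx) -> float:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetInitialTransform(tx, inPlace=False)
        return reg.MetricEvaluate(fix_img, mov_img)

    center = tuple(float(c) for c in fixed.grid.center_mm)
    rigid0 = sitk.Euler3DTransform()
    rigid0.SetCenter(center)
    identity_metric = _metric(rigid0)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetOptimizerAsGradientDescentLineSearch(
        learningRate=1.0, numberOfIterations=100,
        convergenceMinimumValue=1e-9, convergenceWindowSize=10)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(rigid0, inPlace=False)
    rigid = reg.Execute(fix_img, mov_img)
    if hasattr(rigid, "Downcast"):
        rigid = rigid.Downcast()
    if rigid.GetName() == "CompositeTransform":
        rigid = sitk.CompositeTransform(rigid).GetNthTransform(0).Downcast()

    final_tx: sitk.Transform = rigid
    if do_affine_refine:
        aff0 = sitk.AffineTransform(3)
        aff0.SetCenter(center)
        aff0.SetMatrix(sitk.Euler3DTransform(rigid).GetMatrix())
        aff0.SetTranslation(sitk.Euler3DTransform(rigid).GetTranslation())
        reg2 = sitk.ImageRegistrationMethod()
        reg2.SetMetricAsMeanSquares()
        reg2.SetInterpolator(sitk.sitkLinear)
        reg2.SetShrinkFactorsPerLevel([2, 1])
        reg2.SetSmoothingSigmasPerLevel([1.0, 0.0])
        reg2.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg2.SetOptimizerAsGradientDescentLineSearch(
            learningRate=0.5, numberOfIterations=80,
            convergenceMinimumValue=1e-9, convergenceWindowSize=10)
        reg2.SetOptimizerScalesFromPhysicalShift()
        reg2.SetInitialTransform(aff0, inPlace=False)
        try:
            refined = reg2.Execute(fix_img, mov_img)
            if hasattr(refined, "Downcast"):
                refined = refined.Downcast()
            if refined.GetName() == "CompositeTransform":
                refined = sitk.CompositeTransform(refined).GetNthTransform(0).Downcast()
            if _metric(refined) <= _metric(rigid):
                final_tx = refined
        except RuntimeError:  # pragma: no cover - optimizer failure path
            pass

    if _metric(final_tx) > identity_metric:
        warnings.warn("registration did not improve on identity; returning identity",
                      RegistrationWarning)
        resampled = moving.with_values(np.asarray(moving.values) * scale)
        return AffineTransform.identity(center), resampled

    resampled_img = sitk.Resample(mov_img, fix_img, final_tx, sitk.sitkLinear, 0.0)
    resampled = _from_sitk(resampled_img, fixed.grid, moving.modality_tag)

    # sitk transform maps fixed-space points to moving-space; report the
    # forward (moving -> fixed) affine, i.e. the inverse.
    flat = sitk.AffineTransform(3)
    flat.SetCenter(center)
    if isinstance(final_tx, sitk.Euler3DTransform) or final_tx.GetName() == "Euler3DTransform":
        e = sitk.Euler3DTransform(final_tx)
        flat.SetMatrix(e.GetMatrix())
        flat.SetTranslation(e.GetTranslation())
    else:
        a = sitk.AffineTransform(final_tx)
        flat.SetMatrix(a.GetMatrix())
        flat.SetTranslation(a.GetTranslation())
        flat.SetCenter(a.GetCenter())
    A_b = np.asarray(flat.GetMatrix()).reshape(3, 3)
    t_b = np.asarray(flat.GetTranslation())
    c = np.asarray(flat.GetCenter())
    A = np.linalg.inv(A_b)
    t = -A @ t_b
    params = AffineTransform.from_matrix(A, t, center=tuple(c))
    return params, resampled


# ---------------------------------------------------------------------------
# Template and normal database

def build_symmetric_template(vols: list[ImageVolume]) -> ImageVolume:
    """Average the standardized volumes and fold left onto right.

    T = (mean(vols) + flip_left_right(mean(vols))) / 2, so the output is
    exactly mirror-symmetric about the midsagittal plane.
    """
    if not vols:
        raise ValueError("need at least one volume")
    grid = common_grid(vols)
    mean = ImageVolume(grid, np.mean([np.asarray(v.values, dtype=float) for v in vols], axis=0),
                       vols[0].modality_tag)
    folded = flip_left_right(mean)
    return mean.with_values((np.asarray(mean.values) + np.asarray(folded.values)) / 2.0)


@dataclass
class NormalDatabase:
    """Per-voxel control mean and SD with provenance.

    ``mean_vol`` and ``sd_vol`` are in normalized count units (global mean
    scaled to a fixed reference); ``sd_vol`` uses the n-1 (sample) SD.
    """

    mean_vol: ImageVolume
    sd_vol: ImageVolume
    n_subjects: int
    smoothing_fwhm_mm: float = 12.0
    normalization_tag: str = "global-mean-50"

    def __post_init__(self):
        if self.mean_vol.grid != self.sd_vol.grid:
            raise ValueError("mean and SD volumes must share a grid")
        if self.n_subjects < 2:
            raise ValueError("a normal database needs at least 2 subjects")
        sd = np.asarray(self.sd_vol.values)
        if np.nanmin(sd) < -1e-9:
            raise ValueError("SD volume has negative values")

    @property
    def grid(self) -> VolumeGrid:
        return self.mean_vol.grid

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_volume(self.mean_vol, directory / "mean.nii.gz")
        write_volume(self.sd_vol, directory / "sd.nii.gz")
        meta = {
            "n_subjects": self.n_subjects,
            "smoothing_fwhm_mm": self.smoothing_fwhm_mm,
            "normalization_tag": self.normalization_tag,
        }
        (directory / "database.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "NormalDatabase":
        directory = Path(directory)
        meta = json.loads((directory / "database.json").read_text())
        mean_vol = read_volume(directory / "mean.nii.gz", "SPECT")
        sd_vol = read_volume(directory / "sd.nii.gz", "SPECT")
        return cls(mean_vol=mean_vol, sd_vol=sd_vol, **meta)


def build_normal_db(vols: list[ImageVolume], smoothing_fwhm_mm: float = 12.0,
                    normalization_tag: str = "global-mean-50") -> NormalDatabase:
    """Per-voxel mean and sample SD (n-1) of standardized control volumes.

    Inputs must already be standardized, smoothed and count-normalized.
    """
    if len(vols) < 2:
        raise ValueError(f"need >= 2 control volumes, got {len(vols)}")
    grid = common_grid(vols)
    stack = np.stack([np.asarray(v.values, dtype=float) for v in vols])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return NormalDatabase(
        mean_vol=ImageVolume(grid, mean, "SPECT"),
        sd_vol=ImageVolume(grid, sd, "SPECT"),
        n_subjects=len(vols),
        smoothing_fwhm_mm=smoothing_fwhm_mm,
        normalization_tag=normalization_tag,
    )
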