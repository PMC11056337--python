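# Methods

## Scientific model

Cerebral-perfusion SPECT is read against a **normal database**: a per-voxel
mean (μ) and standard deviation (σ) image built from control scans in a
common stereotactic space. A subject scan *s* is converted to a Z-score map

    Z(v) = (μ(v) − s(v)) / σ(v)

so **positive Z means hypoperfusion** relative to controls. In patients with
brain atrophy, cortical voxels in the uncorrected analysis include widened
CSF space; the partial-volume mixture of CSF lowers measured counts and
inflates Z even where remaining tissue perfuses normally. The package
implements an MRI-based correction: a subject-specific **GM+WM brain mask**
derived from the subject's T1 image restricts the comparison domain, so
voxels that are no longer brain tissue are excluded instead of being scored
as hypoperfused. The paired analysis is reported as Mask(−) (no mask) and
Mask(+) (masked).

The per-region effect of the mask is quantified by the **atrophy correction
rate**

    rate = (Z_unmasked − Z_masked) / Z_unmasked × 100  [%]

Positive rate = the unmasked analysis overestimated hypoperfusion. The rate
is scale-invariant in Z and undefined when `Z_unmasked == 0`
(`UndefinedRateError`).

## Pipeline stages and parameters

All numeric constants live in `RunConfig` (`zsmap/config.py`); defaults
follow the routine clinical protocol the package models.

| Parameter | Default | Rationale |
|---|---|---|
| `spect_fwhm_mm` | 12.0 | Isotropic Gaussian smoothing applied to every scan before comparison; brings scans from different resolutions to a common effective resolution and suppresses noise. |
| `analysis_threshold_frac` | 0.35 | Voxels below 35% of the volume maximum are outside the count-normalization set and the analysis domain (background/scalp exclusion). |
| `global_mean_reference` | 50.0 | Each scan is scaled so its mean over the threshold set equals 50 (global-mean count normalization); subjects are normalized against the *template's* threshold set so Mask(−)/Mask(+) share one normalization. |
| `mask_fwhm_mm` | 4.0 | GM+WM probability is smoothed mildly before binarization so the mask tolerates segmentation speckle without eroding cortex. |
| `mask_binarize_threshold` | 0.5 | Majority-tissue rule for mask membership. |
| `sigma_floor_frac` | 1e-3 | Voxels with σ below `1e-3 × 50` are excluded: Z is numerically meaningless where the database is (near-)deterministic. |
| `z_extent` | 2.0 | Extent statistic counts the fraction of region voxels with Z ≥ 2 (conventional two-sigma abnormality cut). |
| `pathological_z_cut` | 0.5 | A region is "at least mildly hypoperfused" when either side's mean Z exceeds 0.5; correction rates are summarized over these regions. |
| `bootstrap_resamples` | 2000 | Paired stratified bootstrap size for AUC differences. |

Statistics use established implementations: `scipy.stats` (paired t,
one-way ANOVA), `statsmodels` (Tukey–Kramer), `scikit-learn`
(`roc_curve`), `SimpleITK` (affine registration), `scikit-learn` KMeans
(T1 three-class segmentation). The trapezoidal AUC over all unique
thresholds equals the normalized Mann–Whitney U statistic; the Youden
cutoff maximizes J = sensitivity + specificity − 1 with ties broken toward
the lower (more sensitive) threshold, using a 1e-12 tolerance so
floating-point rounding cannot hide exact ties.

## The digital phantom

`zsmap.phantom` renders paired SPECT/T1 volumes with voxel-level ground
truth (64³ voxels at 3 mm by default).

What it emulates:

- An ellipsoidal brain (66/80/62 mm semi-axes) with a WM core, lateral
  ventricles, interhemispheric fissure and ten sulcal wedges, surrounded
  by outer CSF.
- **Atrophy** of severity `a ∈ [0, 1]`: CSF spaces widen at grey matter's
  expense (about 19% GM volume loss at `a = 0.5`), with optional
  per-subject jitter.
- A 34-label left–right symmetric sector atlas including analogs of the
  five dementia-related regions (superior parietal, angular, supramarginal,
  precuneus, posterior cingulate).
- SPECT activity 4:1 GM:WM, focal lesions scaling a region's activity by
  `(1 − depth)`, a smooth multiplicative **biological variability field**
  (CV 0.10, 8-mm correlation length), an 8-mm system PSF, and
  multiplicative measurement noise (CV 0.05).
- T1 intensities 1.0/2.5/3.5 for CSF/GM/WM plus additive noise, so the
  KMeans segmentation faces realistic partial-volume mixtures.

What it does **not** emulate: attenuation, scatter, reconstruction
artifacts, anatomical variability of gyral topology, registration error
between subjects (all phantoms share one stereotactic frame), or
non-rigid atrophy topology changes.

### Resolution accounting: `PHANTOM_STUDY_CONFIG`

Phantom studies run with `PHANTOM_STUDY_CONFIG = RunConfig(spect_fwhm_mm=0)`.
The phantom's 8-mm PSF already represents the *final effective resolution*
of a processed scan. Applying the clinical 12-mm processing smoothing on
top would double-count resolution: after ~14-mm total smoothing the noise
that remains is almost entirely long-range, so a 15-control database's
regional error no longer averages down within a region (empirically ~0.15
SD per region), and even a no-signal cohort shows spurious regional Z near
the acceptance threshold. With the PSF as the only resolution step, the
no-signal null holds with margin (worst regional group mean ≈ 0.15 across
several master seeds at n = 15 controls / 40 patients). Clinical use of
real, unsmoothed scans keeps the 12-mm default.

## Numerical choices

- Volumes are float32 on disk (NIfTI via nibabel), float64 in memory.
- FWHM→σ conversion uses `1/(2·sqrt(2·ln 2)) ≈ 1/2.3548`.
- The left–right axis is array axis 0 (RAS); the symmetric template is the
  exact mean of the group average and its flip, so template symmetry is
  bitwise.
- Sample SDs use `ddof=1` throughout (database σ, rate summaries).
- Registration (`register_affine`) reports the transform mapping the
  moving image onto the fixed image; recovering a content shift of +t
  therefore yields a reported translation of −t.

## Limitations

- The phantom is stylized; absolute Z magnitudes and correction rates on
  it are not calibrated to any patient population.
- Atrophy correction via domain masking addresses *where* comparison
  happens; it does not correct partial-volume underestimation *inside*
  the mask.
- The bundled reference table ships group-level summaries only; no
  subject-level reanalysis of any clinical cohort is possible from it.
- The segmentation is a three-class intensity KMeans; it is adequate for
  the phantom's contrast and noise, not a general-purpose MR segmenter.
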