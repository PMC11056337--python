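"""Regional statistics on Z-score maps.

Per-ROI mean Z and extent (%) with left/right averaging, selection of
at-least-pathological regions (Z > 0.5 on either side), the atrophy
correction rate

    rate = (Z_unmasked - Z_masked) / Z_unmasked * 100   [%]

(positive: the uncorrected analysis overestimated hypoperfusion), and the
cross-group aggregation conventions used to summarize the five
dementia-related regions (superior parietal lobule, angular gyrus,
supramarginal gyrus, precuneus, posterior cingulate cortex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import ImageVolume, read_volume, write_volume
from .zscore import ZScoreMap

__all__ = [
    "ROIAtlas",
    "RegionStats",
    "AtrophyCorrectionRecord",
    "UndefinedRateError",
    "MissingRegionWarning",
    "DEMENTIA_REGIONS",
    "regional_stats",
    "bilateral_average",
    "select_pathological",
    "atrophy_correction_rate",
    "aggregate_dementia_regions",
    "DementiaRegionSummary",
    "load_reference_group_table",
]

DEMENTIA_REGIONS = (
    "superior_parietal",
    "angular",
    "supramarginal",
    "precuneus",
    "posterior_cingulate",
)


class UndefinedRateError(ZeroDivisionError):
    """Atrophy correction rate is undefined for a zero unmasked Z-score."""


class MissingRegionWarning(UserWarning):
    pass


@dataclass
class ROIAtlas:
    """Integer label volume plus a region table with left/right pairing.

    ``regions`` columns: label (int), name (str), hemisphere ('L'/'R'/
    'midline'), partner_label (int or <NA>), dementia_related (bool).
    """

    labels: ImageVolume
    regions: pd.DataFrame

    def __post_init__(self):
        req = {"label", "name", "hemisphere", "partner_label", "dementia_related"}
        missing = req - set(self.regions.columns)
        if missing:
            raise ValueError(f"region table missing columns {sorted(missing)}")
        self.regions = self.regions.copy()
        self.regions["partner_label"] = self.regions["partner_label"].astype("Int64")
        table_labels = set(self.regions["label"].astype(int))
        present = set(np.unique(np.asarray(self.labels.values))) - {0}
        unknown = present - table_labels
        if unknown:
            raise ValueError(f"label volume contains labels absent from table: {sorted(unknown)}")
        by_label = self.regions.set_index("label")
        for _, row in self.regions.iterrows():
            p = row["partner_label"]
            if pd.isna(p):
                continue
            if int(p) not in by_label.index or int(by_label.loc[int(p), "partner_label"]) != int(row["label"]):
                raise ValueError(f"asymmetric L/R pairing for label {row['label']}")

    @property
    def grid(self):
        return self.labels.grid

    def label_for(self, name: str, hemisphere: str) -> int:
        sel = self.regions[(self.regions["name"] == name)
                           & (self.regions["hemisphere"] == hemisphere)]
        if len(sel) != 1:
            raise KeyError(f"no unique region {name!r}/{hemisphere!r}")
        return int(sel["label"].iloc[0])

    def labels_for_name(self, name: str) -> list[int]:
        sel = self.regions[self.regions["name"] == name]
        if sel.empty:
            raise KeyError(f"unknown region {name!r}")
        return [int(v) for v in sel["label"]]

    def region_names(self) -> list[str]:
        return list(dict.fromkeys(self.regions["name"]))

    def dementia_region_names(self) -> list[str]:
        return list(dict.fromkeys(self.regions.loc[self.regions["dementia_related"], "name"]))

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_volume(self.labels, directory / "atlas_labels.nii.gz")
        self.regions.to_csv(directory / "atlas_regions.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ROIAtlas":
        directory = Path(directory)
        labels = read_volume(directory / "atlas_labels.nii.gz", "label")
        regions = pd.read_csv(directory / "atlas_regions.csv")
        return cls(labels=labels, regions=regions)


@dataclass
class RegionStats:
    """Mean Z and extent (%) of one region-side on one Z map."""

    region: str
    side: str  # 'L', 'R', 'midline' or 'bilateral'
    mean_z: float
    extent_pct: float
    n_voxels: int
    masked_variant: bool = False

    def __post_init__(self):
        if self.n_voxels <= 0:
            raise ValueError("RegionStats requires at least one voxel")
        if not 0.0 <= self.extent_pct <= 100.0:
            raise ValueError(f"extent must be in [0, 100], got {self.extent_pct}")


@dataclass
class AtrophyCorrectionRecord:
    """Regional Mask(-)/Mask(+) Z pair and the correction rate linking them."""

    region: str
    z_unmasked: float
    z_masked: float
    rate_pct: float

    @classmethod
    def from_pair(cls, region: str, z_unmasked: float, z_masked: float) -> "AtrophyCorrectionRecord":
        return cls(region, z_unmasked, z_masked,
                   atrophy_correction_rate(z_unmasked, z_masked))

    @property
    def overestimated(self) -> bool:
        """True when the uncorrected Z overestimated (positive rate)."""
        return self.rate_pct > 0

    @property
    def underestimated(self) -> bool:
        return self.rate_pct < 0


def regional_stats(zmap: ZScoreMap, atlas: ROIAtlas, z_extent: float = 2.0) -> list[RegionStats]:
    """Per region-side mean Z and extent over (ROI intersect analysis mask).

    extent_pct = 100 x |{v in ROI ∩ mask : Z(v) >= z_extent}| / |ROI ∩ mask|.
    Regions with an empty intersection are omitted with a
    :class:`MissingRegionWarning` (never reported as silent zeros).
    """
    if zmap.z.grid != atlas.grid:
        raise ValueError("Z map and atlas must share a grid")
    labels = np.asarray(atlas.labels.values)
    inside = zmap.mask_array
    z = zmap.z_array
    out: list[RegionStats] = []
    for _, row in atlas.regions.iterrows():
        sel = (labels == int(row["label"])) & inside
        n = int(sel.sum())
        if n == 0:
            warnings.warn(
                f"region {row['name']}/{row['hemisphere']} has no voxels in the analysis mask",
                MissingRegionWarning,
            )
            continue
        zv = z[sel]
        out.append(RegionStats(
            region=str(row["name"]),
            side=str(row["hemisphere"]),
            mean_z=float(zv.mean()),
            extent_pct=100.0 * float((zv >= z_extent).sum()) / n,
            n_voxels=n,
            masked_variant=zmap.masked_variant,
        ))
    return out


def bilateral_average(stats: list[RegionStats]) -> list[RegionStats]:
    """Collapse L/R pairs to one record averaging mean Z and extent.

    Midline regions pass through; a region with only one side present is
    passed through with a laterality warning.
    """
    by_region: dict[str, dict[str, RegionStats]] = {}
    order: list[str] = []
    for s in stats:
        if s.region not in by_region:
            order.append(s.region)
        by_region.setdefault(s.region, {})[s.side] = s
    out: list[RegionStats] = []
    for name in order:
        sides = by_region[name]
        if "L" in sides and "R" in sides:
            left, right = sides["L"], sides["R"]
            out.append(RegionStats(
                region=name, side="bilateral",
                mean_z=(left.mean_z + right.mean_z) / 2.0,
                extent_pct=(left.extent_pct + right.extent_pct) / 2.0,
                n_voxels=left.n_voxels + right.n_voxels,
                masked_variant=left.masked_variant,
            ))
        elif "midline" in sides:
            out.append(sides["midline"])
        else:
            only = next(iter(sides.values()))
            warnings.warn(f"region {name} present on one side only ({only.side})",
                          MissingRegionWarning)
            out.append(only)
    return out


def select_pathological(stats: list[RegionStats], z_cut: float = 0.5) -> list[RegionStats]:
    """Keep regions whose left or right mean Z strictly exceeds ``z_cut``.

    Operates on per-side statistics; all sides of a selected region are
    returned.
    """
    max_by_region: dict[str, float] = {}
    for s in stats:
        max_by_region[s.region] = max(max_by_region.get(s.region, -np.inf), s.mean_z)
    keep = {name for name, m in max_by_region.items() if m > z_cut}
    return [s for s in stats if s.region in keep]


def atrophy_correction_rate(z_unmasked: float, z_masked: float) -> float:
    """Relative Z reduction (%) produced by the atrophy-correction mask.

    (z_unmasked - z_masked) / z_unmasked * 100.  Positive means the
    uncorrected analysis overestimated; negative, underestimated.  Applies
    to extent (%) values the same way.
    """
    if z_unmasked == 0:
        raise UndefinedRateError("atrophy correction rate undefined for zero unmasked value")
    return (z_unmasked - z_masked) / z_unmasked * 100.0


# ---------------------------------------------------------------------------
# Cross-group aggregation for the five dementia-related regions

@dataclass
class DementiaRegionSummary:
    """Aggregated five-region summary.

    ``average_of_5``: per diagnostic group, the arithmetic mean over the
    five regional group-mean Z-scores, for the unmasked and masked analyses.
    ``region_rates``: per region, mean and sample SD (n-1) across the
    diagnostic groups of that region's per-group atrophy correction rates.
    ``overall_rate_mean``: mean of the five per-region rate means.
    """

    average_of_5: pd.DataFrame
    region_rates: pd.DataFrame
    overall_rate_mean: float
    overall_rate_sd: float


def aggregate_dementia_regions(per_region: pd.DataFrame) -> DementiaRegionSummary:
    """Aggregate per-region, per-group values for the five dementia regions.

    ``per_region`` is tidy with one row per region x group and columns
    ``region``, ``group``, ``z_unmasked``, ``z_masked``, ``rate_pct``.
    """
    req = {"region", "group", "z_unmasked", "z_masked", "rate_pct"}
    missing = req - set(per_region.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    regions = list(dict.fromkeys(per_region["region"]))
    groups = list(dict.fromkeys(per_region["group"]))
    cells = per_region.set_index(["region", "group"])
    for r in regions:
        for g in groups:
            if (r, g) not in cells.index:
                raise ValueError(f"missing cell for region {r!r}, group {g!r}")

    avg5 = (per_region.groupby("group", sort=False)[["z_unmasked", "z_masked"]]
            .mean().loc[groups])

    rr = (per_region.groupby("region", sort=False)["rate_pct"]
          .agg(rate_mean="mean", rate_sd=lambda x: x.std(ddof=1)).loc[regions])

    overall_mean = float(rr["rate_mean"].mean())
    overall_sd = float(rr["rate_mean"].std(ddof=1))
    return DementiaRegionSummary(
        average_of_5=avg5,
        region_rates=rr,
        overall_rate_mean=overall_mean,
        overall_rate_sd=overall_sd,
    )


def load_reference_group_table() -> pd.DataFrame:
    """Bundled published-cohort reference table for the five dementia regions.

    Group-level regional mean Z-scores (Mask(-)/Mask(+), with SDs), cohort
    sizes and per-group atrophy correction rates for cognitively normal,
    MCI and AD cohorts; used by the worked aggregation example.
    """
    with resources.files("zsmap.data").joinpath("dementia_region_reference.csv").open() as fh:
        return pd.read_csv(fh)
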