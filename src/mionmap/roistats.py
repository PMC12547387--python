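"""Regions of interest and per-subcategory t profiles.

ROIs come in two flavors, as in the study: fixed-size spheres centered on
group-map peaks (4.5 mm diameter, which holds exactly 19 voxels on the
1.5 mm functional grid), and per-subject intersections of an atlas field
with the subject's significant Sound-vs-Silence mask (used for A1).
Bilateral regions are stored and reported as two single-hemisphere ROIs.

Profiles are the mean t over ROI voxels of each of the 8
subcategory-vs-silence contrasts, summarized across subjects by mean and
standard error of the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .firstlevel import ContrastMap
from .group_rft import GroupResult
from .phantom_sim import TissueAtlas, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "Roi",
    "SubcategoryProfile",
    "sphere_roi",
    "define_rois",
    "extract_profile",
    "group_profile",
]


@dataclass
class Roi:
    """A named set of voxels with its construction provenance."""

    name: str
    voxels: np.ndarray  # (n, 3) integer indices
    mode: str  # "sphere" | "intersection"
    center: tuple[int, int, int] | None = None
    diameter_mm: float | None = None

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def mask(self, dims) -> np.ndarray:
        m = np.zeros(dims, dtype=bool)
        m[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return m


def sphere_roi(
    center, diameter_mm: float, grid: VolumeGrid, name: str = "sphere"
) -> Roi:
    """Sphere ROI by the voxel-center Euclidean inclusion rule.

    A voxel belongs to the ROI when its center lies within diameter/2 of the
    center voxel's center.  Spheres clipped at the grid edge are allowed but
    logged.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be positive")
    center = tuple(int(c) for c in center)
    dims = grid.dims
    if any(c < 0 or c >= d for c, d in zip(center, dims)):
        raise ValueError(f"center {center} lies outside the grid {dims}")
    radius = diameter_mm / 2.0
    r_vox = int(np.ceil(radius / grid.voxel_size_mm))
    offs = np.mgrid[-r_vox : r_vox + 1, -r_vox : r_vox + 1, -r_vox : r_vox + 1]
    offs = offs.reshape(3, -1).T
    dist = grid.voxel_size_mm * np.linalg.norm(offs, axis=1)
    offs = offs[dist <= radius + 1e-9]
    vox = offs + np.asarray(center)
    inside = np.all((vox >= 0) & (vox < np.asarray(dims)), axis=1)
    if not inside.all():
        logger.warning(
            "sphere ROI %r clipped at the grid edge (%d of %d voxels kept)",
            name, int(inside.sum()), len(vox),
        )
    return Roi(
        name=name,
        voxels=vox[inside].astype(int),
        mode="sphere",
        center=center,
        diameter_mm=diameter_mm,
    )


def _peak_in_label(t_map: np.ndarray, label_mask: np.ndarray) -> tuple[int, int, int]:
    vals = np.where(label_mask, np.where(np.isfinite(t_map), t_map, -np.inf), -np.inf)
    idx = np.unravel_index(int(np.argmax(vals)), t_map.shape)
    return tuple(int(i) for i in idx)


def define_rois(
    atlas: TissueAtlas,
    sound_random: GroupResult,
    catvsnv_fixed: GroupResult,
    subject_sound_maps: dict[str, ContrastMap],
    *,
    sig_t: float = 3.09,
    diameter_mm: float = 4.5,
    atva_centers: dict[str, tuple[int, int, int]] | None = None,
) -> dict[str, Roi]:
    """Build the study's ROI set on the phantom.

    * ``A1_<subject>_<hemi>``: intersection of the A1-like atlas field with
      the subject's significant Sound-vs-Silence voxels (t >= ``sig_t``).
    * ``IC_<hemi>``: sphere at the random-effects Sound-vs-Silence peak
      inside the IC-like label.
    * ``F5_<hemi>``, ``pMTG_<hemi>``: spheres at the fixed-effects
      Macaque-vs-NonVocal peaks inside the respective labels.
    * ``aTVA_<hemi>``: sphere at configured coordinates (defaulting to the
      phantom label's per-hemisphere centroid).
    """
    grid = atlas.grid
    rois: dict[str, Roi] = {}
    hemis = {"L": atlas.hemisphere_mask("L"), "R": atlas.hemisphere_mask("R")}

    a1 = atlas.region_mask("A1-like")
    for subject, smap in subject_sound_maps.items():
        sig = np.where(np.isfinite(smap.t), smap.t, -np.inf) >= sig_t
        for hemi, hmask in hemis.items():
            inter = a1 & sig & hmask
            if not inter.any():
                raise ValueError(
                    f"empty intersection of A1-like field and significant mask "
                    f"for subject {subject} ({hemi})"
                )
            rois[f"A1_{subject}_{hemi}"] = Roi(
                name=f"A1_{subject}_{hemi}",
                voxels=np.argwhere(inter),
                mode="intersection",
            )

    for region, gmap, short in (
        ("IC-like", sound_random, "IC"),
        ("F5-like", catvsnv_fixed, "F5"),
        ("pMTG-like", catvsnv_fixed, "pMTG"),
    ):
        label = atlas.region_mask(region)
        for hemi, hmask in hemis.items():
            sub = label & hmask
            if not sub.any():
                raise ValueError(f"label {region} has no voxels in hemisphere {hemi}")
            center = _peak_in_label(gmap.t, sub)
            rois[f"{short}_{hemi}"] = sphere_roi(
                center, diameter_mm, grid, name=f"{short}_{hemi}"
            )

    atva = atlas.region_mask("aTVA-like")
    for hemi, hmask in hemis.items():
        if atva_centers is not None and hemi in atva_centers:
            center = atva_centers[hemi]
        else:
            coords = np.argwhere(atva & hmask)
            if coords.size == 0:
                raise ValueError(f"aTVA-like label empty in hemisphere {hemi}")
            center = tuple(int(round(x)) for x in coords.mean(axis=0))
        rois[f"aTVA_{hemi}"] = sphere_roi(center, diameter_mm, grid, name=f"aTVA_{hemi}")
    return rois


def extract_profile(
    subcategory_maps: dict[str, ContrastMap], roi: Roi, stat: str = "mean"
) -> dict[str, float]:
    """Per-subcategory ROI value: mean (default) or peak t over ROI voxels."""
    out = {}
    for sub, cmap in subcategory_maps.items():
        dims = cmap.shape
        if np.any(roi.voxels >= np.asarray(dims)) or np.any(roi.voxels < 0):
            raise ValueError(f"ROI {roi.name!r} lies outside the map grid {dims}")
        vals = cmap.t[roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]]
        out[sub] = float(np.nanmax(vals) if stat == "peak" else np.nanmean(vals))
    return out


@dataclass
class SubcategoryProfile:
    """Group summary (mean +/- SEM across subjects) of an ROI's profile."""

    roi_name: str
    per_subject: pd.DataFrame = field(repr=False)  # rows subjects, cols subcats
    mean: pd.Series = field(repr=False)
    sem: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi": self.roi_name, "subcategory": self.mean.index,
             "mean_t": self.mean.values, "sem_t": self.sem.values}
        )


def group_profile(per_subject_values: pd.DataFrame, roi_name: str = "") -> SubcategoryProfile:
    """Mean and standard error of the mean across subjects per subcategory.

    ``per_subject_values``: one row per subject, one column per subcategory.
    """
    n = len(per_subject_values)
    if n < 2:
        raise ValueError("group profile needs >= 2 subjects (SEM undefined otherwise)")
    mean = per_subject_values.mean(axis=0)
    sem = per_subject_values.std(axis=0, ddof=1) / np.sqrt(n)
    return SubcategoryProfile(
        roi_name=roi_name, per_subject=per_subject_values, mean=mean, sem=sem
    )


def plot_profile(profile: SubcategoryProfile, path) -> None:
    """Bar plot of an ROI's subcategory profile (mean +/- SEM)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(profile.mean))
    ax.bar(x, profile.mean.values, yerr=profile.sem.values, capsize=3)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(profile.mean.index, rotation=45, ha="right")
    ax.set_ylabel("t value")
    ax.set_title(profile.roi_name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
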