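"""Synthetic cohorts for the anesthetized-macaque auditory fMRI pipeline.

This module generates everything the downstream analysis needs without any
downloads: a digital tissue phantom with named auditory regions, run designs
that follow the clustered sparse-sampling protocol of the study (48 cycles of
a 3.5 s scanner-silent gap followed by a 7-volume acquisition cluster at
646 ms spacing; 32 stimulus blocks and 16 silent blocks per run; 100-250 ms
onset jitter), and 4-D volumes whose signal structure is known exactly.

Signal model per voxel:

    y(t) = baseline * (1 + sum_c a(region, c) * r_c(t)) + drift(t)
           + AR(1) noise + compartment nuisance

where ``a`` is the planted neural amplitude (fraction of baseline) and
``r_c`` is the condition-c boxcar convolved with the reversed-sign MION
response function, evaluated at the acquisition timestamps.  A positive
neural amplitude therefore *lowers* the measured intensity, as the contrast
agent does.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so any run of a cohort can be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import hemodynamics
from .hemodynamics import ResponseFunction

logger = logging.getLogger(__name__)

__all__ = [
    "BACKGROUND",
    "GRAY",
    "WHITE",
    "CSF",
    "VolumeGrid",
    "RegionSpec",
    "TissueAtlas",
    "StimulusCatalog",
    "ProtocolConfig",
    "Block",
    "AcquisitionCluster",
    "RunDesign",
    "GroundTruth",
    "RunImage",
    "default_catalog",
    "default_region_specs",
    "make_phantom",
    "default_truth",
    "make_run_design",
    "simulate_run",
    "simulate_cohort",
]

# tissue class codes in the label volume; named regions use codes >= 10
BACKGROUND, GRAY, WHITE, CSF = 0, 1, 2, 3
REGION_CODE_START = 10


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic voxel grid of the functional space."""

    dims: tuple[int, int, int]
    voxel_size_mm: float = 1.5
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) != d or d < 8 for d in self.dims):
            raise ValueError(f"dims must be 3 integers >= 8, got {self.dims}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def affine(self) -> np.ndarray:
        A = np.diag([self.voxel_size_mm] * 3 + [1.0])
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))


@dataclass(frozen=True)
class RegionSpec:
    """A named gray-matter region, as a union of spherical blobs.

    ``centers`` holds one voxel-index triple per blob (two for a bilateral
    region), ``radius_vox`` the blob radius in voxels.
    """

    name: str
    centers: tuple[tuple[int, int, int], ...]
    radius_vox: float


@dataclass
class TissueAtlas:
    """Label volume with tissue classes and named gray-matter regions."""

    grid: VolumeGrid
    labels: np.ndarray
    region_table: dict[str, int]

    def region_mask(self, name: str) -> np.ndarray:
        if name not in self.region_table:
            raise KeyError(f"unknown region {name!r}; have {sorted(self.region_table)}")
        return self.labels == self.region_table[name]

    @property
    def gray_mask(self) -> np.ndarray:
        """Gray matter including all named regions (the 'whole brain' of the
        jackknife and peak searches)."""
        m = self.labels == GRAY
        for code in self.region_table.values():
            m |= self.labels == code
        return m

    @property
    def white_mask(self) -> np.ndarray:
        return self.labels == WHITE

    @property
    def csf_mask(self) -> np.ndarray:
        return self.labels == CSF

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Left/right split along the first axis at the midline."""
        x = np.arange(self.grid.dims[0])[:, None, None]
        half = self.grid.dims[0] / 2.0
        m = x < half if side == "L" else x >= half
        return np.broadcast_to(m, self.grid.dims)


def default_region_specs(grid: VolumeGrid) -> list[RegionSpec]:
    """Default phantom regions, scaled to the grid.

    Bilateral blobs emulate: A1-like primary auditory cortex, IC-like
    inferior colliculus, MGB-like medial geniculate body, F5-like ventral
    premotor cortex, pMTG-like posterior middle temporal gyrus, and an
    aTVA-like anterior temporal label (present only as an anatomical
    placeholder).
    """
    nx, ny, nz = grid.dims
    s = nx / 24.0

    def c(fx, fy, fz):
        return (int(round(fx * nx)), int(round(fy * ny)), int(round(fz * nz)))

    return [
        RegionSpec("A1-like", (c(0.250, 0.333, 0.444), c(0.708, 0.333, 0.444)), 2.3 * s),
        RegionSpec("IC-like", (c(0.417, 0.542, 0.389), c(0.542, 0.542, 0.389)), 1.6 * s),
        RegionSpec("F5-like", (c(0.208, 0.667, 0.556), c(0.750, 0.667, 0.556)), 2.0 * s),
        RegionSpec("pMTG-like", (c(0.208, 0.500, 0.667), c(0.750, 0.500, 0.667)), 1.9 * s),
        RegionSpec("aTVA-like", (c(0.292, 0.167, 0.556), c(0.667, 0.167, 0.556)), 2.0 * s),
        RegionSpec("MGB-like", (c(0.417, 0.667, 0.500), c(0.583, 0.667, 0.500)), 1.4 * s),
    ]


def _sphere_voxels(grid: VolumeGrid, center, radius_vox: float) -> np.ndarray:
    r = int(np.ceil(radius_vox))
    offs = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    offs = offs[np.linalg.norm(offs, axis=1) <= radius_vox + 1e-9]
    vox = offs + np.asarray(center)
    return vox


def make_phantom(
    grid: VolumeGrid | None = None,
    region_specs: Sequence[RegionSpec] | None = None,
) -> TissueAtlas:
    """Build the digital tissue phantom.

    The volume is a one-voxel background shell around gray matter, with a
    white-matter slab in the lower third and a CSF slab near the top (both
    thick enough to survive 3 mm erosion on the default grid).  Named regions
    are carved into gray matter; overlapping region definitions raise an
    error naming both regions.
    """
    if grid is None:
        grid = VolumeGrid((24, 24, 18))
    if region_specs is None:
        region_specs = default_region_specs(grid)

    nx, ny, nz = grid.dims
    labels = np.full(grid.dims, BACKGROUND, dtype=np.int16)
    labels[1:-1, 1:-1, 1:-1] = GRAY

    def box(f0, f1, axis_lo_frac, axis_hi_frac):
        # x/y extent f0..f1, z extent axis_lo..axis_hi (fractions of dims),
        # clamped to the interior so the background shell stays intact
        x0, x1 = int(round(f0 * nx)), int(round(f1 * nx))
        y0, y1 = int(round(f0 * ny)), int(round(f1 * ny))
        z0, z1 = int(round(axis_lo_frac * nz)), int(round(axis_hi_frac * nz))
        clamp = lambda lo, hi, n: (max(lo, 1), min(hi + 1, n - 1))
        return tuple(
            slice(*clamp(lo, hi, n))
            for lo, hi, n in ((x0, x1, nx), (y0, y1, ny), (z0, z1, nz))
        )

    labels[box(0.125, 0.833, 0.111, 0.222)] = WHITE
    labels[box(0.125, 0.833, 0.778, 0.889)] = CSF

    region_table: dict[str, int] = {}
    owner = np.full(grid.dims, -1, dtype=int)  # which spec claimed each voxel
    for i, spec in enumerate(region_specs):
        code = REGION_CODE_START + i
        n_painted = 0
        for center in spec.centers:
            vox = _sphere_voxels(grid, center, spec.radius_vox)
            if np.any(vox < 0) or np.any(vox >= np.array(grid.dims)):
                raise ValueError(f"region {spec.name!r} does not fit inside the grid")
            ix, iy, iz = vox.T
            clash = owner[ix, iy, iz]
            hit = clash >= 0
            if np.any(hit & (clash != i)):
                other = region_specs[int(clash[hit][0])].name
                raise ValueError(
                    f"regions {spec.name!r} and {other!r} overlap at a voxel"
                )
            owner[ix, iy, iz] = i
            gray_here = labels[ix, iy, iz] == GRAY
            labels[ix[gray_here], iy[gray_here], iz[gray_here]] = code
            n_painted += int(gray_here.sum())
        if n_painted == 0:
            raise ValueError(f"region {spec.name!r} is empty after tissue masking")
        region_table[spec.name] = code
    return TissueAtlas(grid=grid, labels=labels, region_table=region_table)


# ---------------------------------------------------------------------------
# stimulus catalog


MAIN_CATEGORIES = ("macaque_vocal", "non_vocal")

_SUBCATEGORIES = {
    "coos": "macaque_vocal",
    "grunts": "macaque_vocal",
    "barks": "macaque_vocal",
    "screams": "macaque_vocal",
    "natural_living": "non_vocal",
    "natural_nonliving": "non_vocal",
    "artificial_human": "non_vocal",
    "artificial_other": "non_vocal",
}


@dataclass(frozen=True)
class StimulusCatalog:
    """48 stimuli: 8 subcategories of 6, nested in 2 main categories."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        subs = t.groupby("subcategory", sort=False)
        if len(subs) != 8:
            raise ValueError(f"expected 8 subcategories, got {len(subs)}")
        if not all(len(g) == 6 for _, g in subs):
            raise ValueError("each subcategory must contain exactly 6 stimuli")
        if len(t) != 48:
            raise ValueError("expected 48 stimuli in total")
        mapping = t.groupby("subcategory")["main_category"].nunique()
        if not (mapping == 1).all():
            raise ValueError("each subcategory must map to exactly one main category")

    @property
    def subcategories(self) -> list[str]:
        return list(dict.fromkeys(self.table["subcategory"]))

    @property
    def main_of(self) -> dict[str, str]:
        return dict(zip(self.table["subcategory"], self.table["main_category"]))

    def stimuli_of(self, subcategory: str) -> list[str]:
        return list(self.table.loc[self.table["subcategory"] == subcategory, "stimulus_id"])


def default_catalog(stimulus_duration_s: float = 0.5) -> StimulusCatalog:
    rows = []
    for sub, main in _SUBCATEGORIES.items():
        for i in range(6):
            rows.append(
                {
                    "stimulus_id": f"{sub}_{i + 1:02d}",
                    "subcategory": sub,
                    "main_category": main,
                    "duration_s": stimulus_duration_s,
                }
            )
    return StimulusCatalog(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# run design


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the clustered sparse-sampling protocol."""

    n_cycles: int = 48
    cluster_volumes: int = 7
    volume_spacing_s: float = 0.646
    gap_s: float = 3.5
    jitter_min_s: float = 0.100
    jitter_max_s: float = 0.250
    n_stimulus_blocks: int = 32
    n_silence_blocks: int = 16
    stimuli_per_block: int = 6
    stimulus_duration_s: float = 0.5
    isi_s: float = 0.05

    @property
    def block_duration_s(self) -> float:
        n = self.stimuli_per_block
        return n * self.stimulus_duration_s + (n - 1) * self.isi_s

    @property
    def cycle_duration_s(self) -> float:
        return self.gap_s + self.cluster_volumes * self.volume_spacing_s

    @property
    def run_duration_s(self) -> float:
        return self.n_cycles * self.cycle_duration_s


@dataclass(frozen=True)
class Block:
    onset_s: float
    duration_s: float
    condition: str  # subcategory name or "silence"
    jitter_s: float
    stimulus_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class AcquisitionCluster:
    start_time_s: float
    n_volumes: int
    volume_spacing_s: float

    @property
    def volume_times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_volumes) * self.volume_spacing_s


@dataclass(frozen=True)
class RunDesign:
    """Timed schedule of one functional run."""

    clusters: tuple[AcquisitionCluster, ...]
    blocks: tuple[Block, ...]
    run_duration_s: float
    protocol: ProtocolConfig

    @property
    def volume_times(self) -> np.ndarray:
        return np.concatenate([c.volume_times for c in self.clusters])

    @property
    def n_volumes(self) -> int:
        return sum(c.n_volumes for c in self.clusters)

    def stimulus_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.condition != "silence"]


def make_run_design(
    seed: int,
    protocol: ProtocolConfig | None = None,
    catalog: StimulusCatalog | None = None,
) -> RunDesign:
    """Randomize one run's block schedule under the protocol's constraints.

    Condition order is a seeded uniformly random permutation of 32 stimulus
    blocks (4 per subcategory) and 16 silence blocks, one block per
    scanner-silent gap.  Stimulus blocks start 100-250 ms (jittered) after
    the end of the previous acquisition cluster.
    """
    protocol = protocol or ProtocolConfig()
    catalog = catalog or default_catalog(protocol.stimulus_duration_s)
    subcats = catalog.subcategories
    if protocol.n_stimulus_blocks % len(subcats):
        raise ValueError("n_stimulus_blocks must be a multiple of the subcategory count")
    if protocol.n_stimulus_blocks + protocol.n_silence_blocks != protocol.n_cycles:
        raise ValueError("block counts must sum to the number of cycles")
    if protocol.jitter_max_s + protocol.block_duration_s > protocol.gap_s + 1e-9:
        raise ValueError(
            "stimulus block cannot fit in the silent gap: "
            f"jitter_max + block duration = "
            f"{protocol.jitter_max_s + protocol.block_duration_s:g} s > gap "
            f"{protocol.gap_s:g} s"
        )

    rng = np.random.default_rng(seed)
    per_sub = protocol.n_stimulus_blocks // len(subcats)
    order = subcats * per_sub + ["silence"] * protocol.n_silence_blocks
    order = [order[i] for i in rng.permutation(len(order))]
    stim_lists = {sub: catalog.stimuli_of(sub) for sub in subcats}

    clusters = []
    blocks = []
    for i, cond in enumerate(order):
        gap_start = i * protocol.cycle_duration_s
        cluster_start = gap_start + protocol.gap_s
        clusters.append(
            AcquisitionCluster(cluster_start, protocol.cluster_volumes, protocol.volume_spacing_s)
        )
        if cond == "silence":
            blocks.append(Block(gap_start, protocol.gap_s, "silence", 0.0))
        else:
            jitter = float(rng.uniform(protocol.jitter_min_s, protocol.jitter_max_s))
            stims = stim_lists[cond]
            stims = tuple(stims[j] for j in rng.permutation(len(stims)))
            blocks.append(
                Block(gap_start + jitter, protocol.block_duration_s, cond, jitter, stims)
            )
    return RunDesign(
        clusters=tuple(clusters),
        blocks=tuple(blocks),
        run_duration_s=protocol.run_duration_s,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# ground truth and simulation


@dataclass(frozen=True)
class GroundTruth:
    """Planted signal, noise and nuisance structure of a synthetic cohort.

    ``amplitudes`` maps region name -> {subcategory -> percent signal
    change}; the sign convention is pre-hemodynamics *neural* amplitude
    (positive = stronger neural response, hence an intensity decrease under
    the contrast agent).

    ``nuisance_gray_leak`` scales how strongly the compartment latents bleed
    into gray matter.  The default 0 confines nuisance strictly to the
    white/CSF compartments; a positive value emulates brain-wide
    physiological noise that the compartment PCA can measure and remove.
    """

    amplitudes: Mapping[str, Mapping[str, float]]
    ar1_rho: float = 0.3
    white_sd_pct: float = 0.5
    drift_coeffs_pct: tuple[float, ...] = (0.0, 0.2, -0.1, 0.05)
    n_white_components: int = 2
    n_csf_components: int = 2
    nuisance_sd_pct: float = 1.5
    nuisance_gray_leak: float = 0.0
    baseline: float = 1000.0

    def __post_init__(self):
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        for region, table in self.amplitudes.items():
            for sub, a in table.items():
                if not np.isfinite(a):
                    raise ValueError(f"amplitude for ({region}, {sub}) is not finite")

    def amplitude(self, region: str, subcategory: str) -> float:
        table = self.amplitudes.get(region, {})
        return float(table.get(subcategory, table.get("*", 0.0)))


def default_truth(catalog: StimulusCatalog | None = None) -> GroundTruth:
    """Default planted effects mirroring the study's qualitative findings:

    * A1-like and IC-like respond (+1% signal change) to every subcategory;
    * F5-like and pMTG-like respond positively to macaque vocalizations and
      negatively to non-vocal sounds;
    * aTVA-like shows a weak, unselective response (vocalization selectivity
      there is absent under anesthesia).
    """
    catalog = catalog or default_catalog()
    main_of = catalog.main_of
    sel = lambda pos, neg: {
        sub: (pos if main_of[sub] == "macaque_vocal" else neg)
        for sub in catalog.subcategories
    }
    return GroundTruth(
        amplitudes={
            "A1-like": {"*": 1.0},
            "IC-like": {"*": 1.0},
            "MGB-like": {"*": 1.0},
            "F5-like": sel(0.5, -0.5),
            "pMTG-like": sel(0.4, -0.4),
            "aTVA-like": {"*": 0.2},
        }
    )


@dataclass
class RunImage:
    """One simulated run: 4-D intensities plus acquisition timestamps."""

    data: np.ndarray
    timestamps_s: np.ndarray
    grid: VolumeGrid
    subject_id: str = "sub-01"
    run_id: str = "run-01"
    seed: int | None = None

    def __post_init__(self):
        if self.data.shape[-1] != self.timestamps_s.size:
            raise ValueError("volume count does not match timestamp count")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def _ar1_noise(rng, shape, rho, sd):
    """Stationary AR(1) noise with innovation scaled to marginal sd."""
    n_t = shape[-1]
    burn = 50
    eps = rng.standard_normal(shape[:-1] + (n_t + burn,))
    if rho != 0.0:
        eps = sp_signal.lfilter([1.0], [1.0, -rho], eps, axis=-1)
        eps *= np.sqrt(1.0 - rho**2)  # unit marginal variance after filtering
    return sd * eps[..., burn:]


def _smooth_latents(rng, k, n_t, sd):
    """Slowly varying latent nuisance time courses (AR(0.8)), sd-scaled."""
    if k == 0:
        return np.zeros((0, n_t))
    lat = _ar1_noise(rng, (k, n_t), 0.8, 1.0)
    lat -= lat.mean(axis=1, keepdims=True)
    lat /= np.maximum(lat.std(axis=1, keepdims=True), 1e-12)
    return sd * lat


def simulate_run(
    atlas: TissueAtlas,
    design: RunDesign,
    truth: GroundTruth,
    rf: ResponseFunction,
    seed: int,
    catalog: StimulusCatalog | None = None,
    subject_id: str = "sub-01",
    run_id: str = "run-01",
) -> tuple[RunImage, dict]:
    """Simulate one functional run on the phantom.

    Returns the run image and a truth record (regressors and latents used),
    handy for oracle tests.
    """
    if rf.step_s > 0.05:
        raise ValueError("response function must be sampled at <= 50 ms steps")
    catalog = catalog or default_catalog(design.protocol.stimulus_duration_s)
    for region in truth.amplitudes:
        if region not in atlas.region_table:
            raise KeyError(f"ground truth references unknown region {region!r}")

    subcats = catalog.subcategories
    reg, names, timestamps = hemodynamics.build_task_regressors(design, rf, subcats)
    n_t = timestamps.size
    rng = np.random.default_rng(seed)
    grid = atlas.grid

    data = np.zeros(grid.dims + (n_t,), dtype=np.float64)
    brain = atlas.brain_mask
    data[brain] = truth.baseline

    # planted regional responses
    for region in truth.amplitudes:
        mask = atlas.region_mask(region)
        amps = np.array([truth.amplitude(region, s) for s in subcats]) / 100.0
        ts = truth.baseline * (1.0 + reg @ amps)
        data[mask] = ts

    # slow scanner drift, shared across the brain (Legendre in scaled time)
    if any(c != 0.0 for c in truth.drift_coeffs_pct):
        x = 2.0 * (timestamps - timestamps[0]) / (timestamps[-1] - timestamps[0]) - 1.0
        drift = np.polynomial.legendre.legval(x, truth.drift_coeffs_pct)
        data[brain] += truth.baseline * drift / 100.0

    # compartment nuisance: latents live in white/CSF, optionally leaking
    # into gray matter (physiological-noise emulation)
    latents = {}
    for comp, mask, k in (
        ("white", atlas.white_mask, truth.n_white_components),
        ("csf", atlas.csf_mask, truth.n_csf_components),
    ):
        lat = _smooth_latents(rng, k, n_t, truth.nuisance_sd_pct / 100.0 * truth.baseline)
        latents[comp] = lat
        if k == 0:
            continue
        nv = int(mask.sum())
        loadings = rng.normal(1.0, 0.3, size=(nv, k))
        data[mask] += loadings @ lat
        if truth.nuisance_gray_leak > 0.0:
            gm = atlas.gray_mask
            ng = int(gm.sum())
            gl = truth.nuisance_gray_leak * np.abs(rng.normal(1.0, 0.2, size=(ng, k)))
            data[gm] += gl @ lat

    # AR(1) + white measurement noise, brain voxels only
    if truth.white_sd_pct > 0.0:
        sd = truth.white_sd_pct / 100.0 * truth.baseline
        data[brain] += _ar1_noise(rng, (int(brain.sum()), n_t), truth.ar1_rho, sd)

    image = RunImage(
        data=data,
        timestamps_s=timestamps,
        grid=grid,
        subject_id=subject_id,
        run_id=run_id,
        seed=seed,
    )
    record = {"regressors": reg, "regressor_names": names, "latents": latents}
    return image, record


def _draw_run_counts(rng, n_subjects: int, median: int = 12, spread: int = 4) -> np.ndarray:
    """Per-subject run counts with the configured median (default 12)."""
    counts = median + rng.integers(-spread, spread + 1, size=n_subjects)
    shift = median - int(np.median(counts))
    return np.maximum(counts + shift, 1)


def simulate_cohort(
    n_subjects: int,
    runs_per_subject: int | Sequence[int] | None,
    truth: GroundTruth,
    seed: int,
    out_dir,
    atlas: TissueAtlas | None = None,
    protocol: ProtocolConfig | None = None,
    rf: ResponseFunction | None = None,
    catalog: StimulusCatalog | None = None,
) -> pd.DataFrame:
    """Simulate a cohort and write it to disk (NIfTI volumes, TSV events,
    atlas, truth record and a manifest).  Returns the manifest."""
    from . import cli_io

    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    atlas = atlas or make_phantom()
    protocol = protocol or ProtocolConfig()
    rf = rf or hemodynamics.mion_rf()
    catalog = catalog or default_catalog(protocol.stimulus_duration_s)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    count_rng = np.random.default_rng(master.spawn(1)[0])
    if runs_per_subject is None:
        counts = _draw_run_counts(count_rng, n_subjects)
    elif np.isscalar(runs_per_subject):
        counts = np.full(n_subjects, int(runs_per_subject))
    else:
        counts = np.asarray(runs_per_subject, dtype=int)
        if counts.size != n_subjects:
            raise ValueError("runs_per_subject length must equal n_subjects")
    if np.any(counts < 1):
        raise ValueError("every subject needs at least one run")

    cli_io.write_volume(atlas.labels.astype(np.int16), atlas.grid, out_dir / "atlas.nii.gz")
    cli_io.write_truth(truth, out_dir / "truth.yaml")

    rows = []
    subject_seqs = master.spawn(n_subjects)
    for si, (sseq, n_runs) in enumerate(zip(subject_seqs, counts)):
        subject = f"sub-{si + 1:02d}"
        run_seqs = sseq.spawn(int(n_runs))
        for ri, rseq in enumerate(run_seqs):
            run = f"run-{ri + 1:02d}"
            run_seed = int(rseq.generate_state(1)[0] % (2**31))
            design = make_run_design(run_seed, protocol, catalog)
            image, _ = simulate_run(
                atlas, design, truth, rf, run_seed, catalog, subject, run
            )
            img_path = out_dir / f"{subject}_{run}_bold.nii.gz"
            ev_path = out_dir / f"{subject}_{run}_events.tsv"
            try:
                cli_io.write_volume(image.data.astype(np.float32), atlas.grid, img_path)
                cli_io.write_events(design, catalog, ev_path)
            except OSError as exc:
                raise OSError(f"failed writing cohort file {exc.filename}: {exc}") from exc
            rows.append(
                {
                    "subject_id": subject,
                    "run_id": run,
                    "image": img_path.name,
                    "events": ev_path.name,
                    "seed": run_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
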