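"""Group maps and family-wise error control via Gaussian random field theory.

Two pooling models are provided: fixed effects (inverse-variance pooling of
subject maps; inference generalizes to the sampled subjects only) and random
effects (a one-sample analysis of subject effect maps, df = n - 1).

Multiple-comparison control follows the classic unified random-field
approach: the expected Euler characteristic of the thresholded t field,

    E[EC(t)] = sum_d R_d * rho_d(t),    d = 0..3,

approximates the family-wise probability of any suprathreshold peak, where
R_d are the resel counts of the search region and rho_d the EC densities of
a t field.  Cluster-size inference uses the expected number of clusters and
expected suprathreshold volume at the cluster-forming threshold, with the
standard exp(-beta * k^(2/3)) tail for the size of a single cluster.

Smoothness (the FWHM of the equivalent Gaussian kernel) is estimated from
the spatial derivatives of standardized residuals, inverting the Gaussian
autocorrelation model exactly at lag one; alternatively a known applied
kernel can be declared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special, stats

from .firstlevel import ContrastMap, combine_runs

logger = logging.getLogger(__name__)

__all__ = [
    "GroupResult",
    "SmoothnessEstimate",
    "ThresholdResult",
    "fixed_effects_group",
    "random_effects_group",
    "estimate_smoothness",
    "ec_density_t",
    "expected_ec",
    "peak_threshold",
    "cluster_forming_threshold",
    "cluster_correct",
]

_T_CAP = 1e6  # stand-in for +inf when between-subject variance degenerates


@dataclass
class GroupResult:
    """Fixed- or random-effects group map."""

    model: str  # "fixed" | "random"
    effect: np.ndarray
    sd: np.ndarray
    t: np.ndarray
    df: int
    n_subjects: int

    @property
    def shape(self):
        return self.effect.shape


def fixed_effects_group(subject_maps: list[ContrastMap]) -> GroupResult:
    """Inverse-variance combination across subject-level maps."""
    combined = combine_runs(subject_maps)
    return GroupResult(
        model="fixed",
        effect=combined.effect,
        sd=combined.sd,
        t=combined.t,
        df=combined.df,
        n_subjects=len(subject_maps),
    )


def random_effects_group(subject_maps: list[ContrastMap]) -> GroupResult:
    """One-sample analysis of subject effect maps: t = mean / (sd / sqrt(n)).

    Requires n >= 3 (df = n - 1 is too small to report below that).  Voxels
    where the between-subject sd is exactly zero get a capped t (with a
    logged warning) if the mean is nonzero, else t = 0.
    """
    n = len(subject_maps)
    if n < 3:
        raise ValueError(f"random-effects analysis needs >= 3 subjects, got {n}")
    shape = subject_maps[0].shape
    for m in subject_maps:
        if m.shape != shape:
            raise ValueError("subject maps are on different grids")
    stack = np.stack([m.effect for m in subject_maps])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / se
    degenerate = (sd == 0) & np.isfinite(mean)
    if np.any(degenerate & (mean != 0)):
        logger.warning(
            "random effects: %d voxels with zero between-subject variance; "
            "t capped at %g", int(np.sum(degenerate & (mean != 0))), _T_CAP
        )
    t = np.where(degenerate, np.sign(mean) * np.where(mean != 0, _T_CAP, 0.0), t)
    return GroupResult(model="random", effect=mean, sd=sd, t=t, df=n - 1, n_subjects=n)


# ---------------------------------------------------------------------------
# smoothness and resels


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM (mm) and resel counts of the search region."""

    fwhm_mm: tuple[float, float, float]
    resels: tuple[float, float, float, float]  # R_0 .. R_3
    n_voxels: int
    volume_mm3: float


def _lattice_counts(mask: np.ndarray):
    """Voxel/edge/face/cube counts of the mask lattice (Worsley counting)."""
    m = mask.astype(bool)
    P = int(m.sum())
    ex = int((m[:-1] & m[1:]).sum())
    ey = int((m[:, :-1] & m[:, 1:]).sum())
    ez = int((m[:, :, :-1] & m[:, :, 1:]).sum())
    fxy = int((m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).sum())
    fxz = int(
        (m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum()
    )
    fyz = int(
        (m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum()
    )
    c = int(
        (
            m[:-1, :-1, :-1]
            & m[1:, :-1, :-1]
            & m[:-1, 1:, :-1]
            & m[:-1, :-1, 1:]
            & m[1:, 1:, :-1]
            & m[1:, :-1, 1:]
            & m[:-1, 1:, 1:]
            & m[1:, 1:, 1:]
        ).sum()
    )
    return P, (ex, ey, ez), (fxy, fxz, fyz), c


def _fwhm_from_residuals(residuals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis FWHM in voxel units from standardized residual derivatives.

    Uses the lag-one autocorrelation of the normalized residual field and
    inverts the Gaussian autocorrelation model rho(1) = exp(-1 / (4 s^2)).
    """
    m = mask.astype(bool)
    ssq = np.sum(residuals**2, axis=-1)
    u = residuals / np.sqrt(np.maximum(ssq, 1e-300))[..., None]
    fwhm = np.empty(3)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        pair = m[tuple(sl_a)] & m[tuple(sl_b)]
        if not pair.any():
            raise ValueError(f"mask has no voxel pairs along axis {ax}")
        d = u[tuple(sl_b)] - u[tuple(sl_a)]
        v = float(np.mean(np.sum(d**2, axis=-1)[pair]))
        rho1 = 1.0 - v / 2.0
        if 0.0 < rho1 < 1.0:
            sigma = np.sqrt(-1.0 / (4.0 * np.log(rho1)))
        else:
            sigma = np.sqrt(np.maximum(4.0 * np.log(2.0) / max(v, 1e-12), 1e-12)) / (
                2.0 * np.sqrt(2.0 * np.log(2.0))
            )
        fwhm[ax] = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    return fwhm


def estimate_smoothness(
    mask: np.ndarray,
    voxel_size_mm: float,
    residuals: np.ndarray | None = None,
    declared_fwhm_mm: float | tuple[float, float, float] | None = None,
) -> SmoothnessEstimate:
    """Estimate the search region's smoothness and resel counts.

    Either ``residuals`` (a 4-D stack of residual images, last axis the
    image index, needing >= 3 images) or a declared applied-kernel FWHM must
    be provided.  R_3 follows volume / prod(FWHM); R_1 and R_2 come from the
    lattice geometry of the mask; R_0 is the Euler characteristic of the
    mask.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("search mask is empty")
    if declared_fwhm_mm is not None:
        fwhm_mm = np.broadcast_to(np.asarray(declared_fwhm_mm, dtype=float), (3,)).copy()
    elif residuals is not None:
        if residuals.shape[-1] < 3:
            raise ValueError("need at least 3 residual images (df >= 3)")
        fwhm_mm = _fwhm_from_residuals(residuals, mask) * voxel_size_mm
    else:
        raise ValueError("provide residuals or a declared FWHM")
    if np.any(fwhm_mm <= 0):
        raise ValueError("estimated FWHM must be positive")

    f = fwhm_mm / voxel_size_mm  # per-axis FWHM in voxel units
    P, (ex, ey, ez), (fxy, fxz, fyz), c = _lattice_counts(mask)
    r0 = float(P - (ex + ey + ez) + (fxy + fxz + fyz) - c)
    r1 = (
        (ex - fxy - fxz + c) / f[0]
        + (ey - fxy - fyz + c) / f[1]
        + (ez - fxz - fyz + c) / f[2]
    )
    r2 = (
        (fxy - c) / (f[0] * f[1])
        + (fxz - c) / (f[0] * f[2])
        + (fyz - c) / (f[1] * f[2])
    )
    volume = P * voxel_size_mm**3
    r3 = volume / float(np.prod(fwhm_mm))
    return SmoothnessEstimate(
        fwhm_mm=tuple(float(x) for x in fwhm_mm),
        resels=(r0, float(r1), float(r2), float(r3)),
        n_voxels=P,
        volume_mm3=volume,
    )


# ---------------------------------------------------------------------------
# EC densities and thresholds


def ec_density_t(t, d: int, df: float):
    """Euler characteristic density of a t field in dimension d (0..3)."""
    t = np.asarray(t, dtype=float)
    v = float(df)
    a = 4.0 * np.log(2.0)
    c = np.power(1.0 + t**2 / v, -(v - 1.0) / 2.0)
    if d == 0:
        return stats.t.sf(t, v)
    if d == 1:
        return np.sqrt(a) / (2.0 * np.pi) * c
    if d == 2:
        b = np.exp(special.gammaln((v + 1.0) / 2.0) - special.gammaln(v / 2.0))
        return a / (2.0 * np.pi) ** 1.5 * c * t * b / np.sqrt(v / 2.0)
    if d == 3:
        return a**1.5 / (2.0 * np.pi) ** 2 * c * ((v - 1.0) * t**2 / v - 1.0)
    raise ValueError("dimension d must be 0..3")


def expected_ec(t, smoothness: SmoothnessEstimate, df: float):
    """Expected Euler characteristic of the thresholded t field."""
    return sum(
        smoothness.resels[d] * ec_density_t(t, d, df) for d in range(4)
    )


def peak_threshold(
    df: float,
    smoothness: SmoothnessEstimate,
    alpha: float = 0.05,
    cap: float = 50.0,
) -> float:
    """Smallest t whose expected EC is <= alpha (family-wise peak control)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not df > 4:
        raise ValueError("df must exceed 4 for a stable t-field threshold")
    grid = np.linspace(0.0, cap, 2001)
    ec = np.asarray(expected_ec(grid, smoothness, df))
    if ec[-1] > alpha:
        raise ValueError(
            f"expected EC still exceeds alpha at the configured cap t={cap}"
        )
    start = int(np.argmax(ec))  # search only the decreasing branch
    if ec[start] <= alpha:
        return float(grid[start])
    fun = lambda t: expected_ec(t, smoothness, df) - alpha
    return float(optimize.brentq(fun, grid[start], cap, xtol=1e-8))


def cluster_forming_threshold(
    cluster_forming_p: float = 0.001,
    df: float | None = None,
) -> float:
    """Primary (cluster-forming) threshold: the upper-tail quantile at
    ``cluster_forming_p`` — standard-normal in the Gaussian limit (default),
    Student t when ``df`` is given."""
    if not (0.0 < cluster_forming_p < 1.0):
        raise ValueError("cluster_forming_p must be in (0, 1)")
    if df is None:
        return float(stats.norm.isf(cluster_forming_p))
    return float(stats.t.isf(cluster_forming_p, df))


@dataclass
class ThresholdResult:
    """Outcome of combined peak / cluster-extent correction."""

    alpha: float
    peak_threshold: float | None
    cluster_forming_t: float
    min_cluster_extent: int
    table: pd.DataFrame
    surviving_mask: np.ndarray
    cluster_labels: np.ndarray


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def cluster_correct(
    t_map: np.ndarray,
    mask: np.ndarray,
    smoothness: SmoothnessEstimate,
    df: float | None = None,
    cluster_forming_p: float = 0.001,
    alpha: float = 0.05,
    connectivity: int = 6,
    peak_t: float | None = None,
    voxel_size_mm: float = 1.5,
) -> ThresholdResult:
    """Label suprathreshold clusters and keep those significant by extent
    (or containing a peak above ``peak_t``).

    The minimum significant extent comes from the random-field expected
    cluster-count/size model at family-wise ``alpha``.  A map with no voxel
    above the cluster-forming threshold yields a valid empty result.
    """
    if t_map.shape != mask.shape:
        raise ValueError("t map and mask are on different grids")
    mask = mask.astype(bool)
    t_c = cluster_forming_threshold(cluster_forming_p, df)

    # expected cluster count and suprathreshold volume under the null
    ec_df = df if df is not None else 1e6
    e_m = max(float(expected_ec(t_c, smoothness, ec_df)), 1e-12)
    e_n = smoothness.n_voxels * cluster_forming_p  # expected voxels above t_c
    beta = (special.gamma(2.5) * e_m / max(e_n, 1e-12)) ** (2.0 / 3.0)
    if e_m <= alpha:
        k_min = 1
    else:
        k_min = int(np.ceil((np.log(e_m / alpha) / beta) ** 1.5))
        k_min = max(k_min, 1)

    supra = np.where(np.isfinite(t_map), t_map, -np.inf) >= t_c
    supra &= mask
    labels, n_lab = ndimage.label(supra, structure=_connectivity_structure(connectivity))

    rows = []
    surviving = np.zeros_like(mask, dtype=bool)
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        size = int(sel.sum())
        tv = np.where(sel, t_map, -np.inf)
        peak_idx = np.unravel_index(int(np.argmax(tv)), t_map.shape)
        peak_val = float(t_map[peak_idx])
        significant = size >= k_min or (peak_t is not None and peak_val >= peak_t)
        if significant:
            surviving |= sel
            rows.append(
                {
                    "label": lab,
                    "n_voxels": size,
                    "peak_t": peak_val,
                    "x_mm": peak_idx[0] * voxel_size_mm,
                    "y_mm": peak_idx[1] * voxel_size_mm,
                    "z_mm": peak_idx[2] * voxel_size_mm,
                }
            )
    table = pd.DataFrame(rows, columns=["label", "n_voxels", "peak_t", "x_mm", "y_mm", "z_mm"])
    return ThresholdResult(
        alpha=alpha,
        peak_threshold=peak_t,
        cluster_forming_t=t_c,
        min_cluster_extent=k_min,
        table=table,
        surviving_mask=surviving,
        cluster_labels=labels,
    )
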