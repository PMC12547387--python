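"""Per-run GLM with AR(1) prewhitening, contrasts and within-subject pooling.

The per-voxel model is ordinary least squares on the design matrix built by
:mod:`mionmap.hemodynamics`.  Serial correlation over the acquired volume
sequence is handled by a two-pass AR(1) scheme: the lag-1 coefficient is
estimated from OLS residuals (optionally regularized by spatial smoothing),
then data and design are prewhitened and refit.  Because voxels sharing a
(binned) AR coefficient share a whitened design, fits are grouped by
coefficient bin, which keeps whole-volume fitting fast.

Sign convention: the reversed-sign response function already encodes the
contrast agent's polarity, so effects and t statistics here are in *neural*
polarity (activation positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hemodynamics import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GlmFit",
    "ContrastMap",
    "smooth_volumes",
    "percent_signal_change",
    "fit_run_glm",
    "compute_contrast",
    "combine_runs",
    "sound_vs_silence_weights",
    "category_contrast_weights",
    "subcategory_weights",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_volumes(data: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Spatially smooth each volume with an isotropic Gaussian kernel.

    ``fwhm_mm = 0`` is the identity; negative values are an error.  Uses a
    normalized separable kernel with reflective boundaries, so a constant
    image is unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
    sigma = (sigma_vox,) * 3 + (0.0,) * (data.ndim - 3)
    return ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")


def percent_signal_change(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    reference: str = "global",
) -> np.ndarray:
    """Scale a run to percent signal change.

    ``reference="global"`` (default) divides by one scalar — the grand mean
    over in-mask voxels and volumes — which leaves task effects unbiased by
    their own contribution to the reference (the phantom's baseline is
    spatially uniform, so this is also the local percent change).
    ``reference="voxel"`` divides by each voxel's temporal mean instead;
    with a dense task design that reference absorbs part of the task signal
    and compresses effect estimates by a few percent.

    Voxels with non-positive reference (background) are set to zero.
    """
    if reference not in ("global", "voxel"):
        raise ValueError("reference must be 'global' or 'voxel'")
    if mask is None:
        mask = data.mean(axis=-1) > 1e-12
    out = np.zeros_like(data, dtype=float)
    if reference == "global":
        if not mask.any():
            return out
        ref = float(data[mask].mean())
        if ref <= 0:
            raise ValueError("non-positive grand mean inside the mask")
        out[mask] = 100.0 * (data[mask] / ref - 1.0)
        return out
    mean = data.mean(axis=-1, keepdims=True)
    ok = mask & (mean > 1e-12).squeeze(-1)
    out[ok] = 100.0 * (data[ok] / mean[ok] - 1.0)
    return out


def _whitening_matrix_apply(arr: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening transform along axis 0."""
    out = np.empty_like(arr, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * arr[0]
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


@dataclass
class GlmFit:
    """Per-voxel regression output for one run.

    ``beta`` has shape (n_columns, n_voxels); spatial shape is kept in
    ``spatial_shape`` so maps can be reshaped back to volumes.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    rho: np.ndarray
    df: int
    design: DesignMatrix
    spatial_shape: tuple[int, ...]
    _bin_index: np.ndarray = field(repr=False)
    _bin_cov: dict = field(repr=False)

    def contrast_variance_scale(self, w: np.ndarray) -> np.ndarray:
        """Per-voxel w' (Xw'Xw)^-1 w under each voxel's whitening."""
        scale = np.empty(self.beta.shape[1])
        for b, cov in self._bin_cov.items():
            scale[self._bin_index == b] = float(w @ cov @ w)
        return scale


def fit_run_glm(
    data: np.ndarray,
    design: DesignMatrix,
    ar_order: int = 1,
    *,
    voxel_size_mm: float | None = None,
    ar_smooth_fwhm_mm: float = 3.0,
    rho_bin: float = 0.01,
) -> GlmFit:
    """Fit the run GLM voxelwise.

    Parameters
    ----------
    data : 4-D (x, y, z, t) or 2-D (voxels, t) array.
    ar_order : 0 for plain OLS, 1 for AR(1) prewhitening (default).
    voxel_size_mm : if given (and data is 4-D), the AR coefficient volume is
        regularized by 3 mm spatial smoothing before whitening; pass
        ``ar_smooth_fwhm_mm=0`` to disable.
    """
    X = design.matrix
    n, p = X.shape
    if data.shape[-1] != n:
        raise ValueError(f"data has {data.shape[-1]} volumes, design expects {n}")
    if n <= p:
        raise ValueError(f"fewer volumes ({n}) than design columns ({p}) + 1")
    if ar_order not in (0, 1):
        raise ValueError("ar_order must be 0 or 1")

    spatial_shape = data.shape[:-1]
    Y = data.reshape(-1, n).T  # (t, voxels)
    nv = Y.shape[1]
    df = n - p

    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta

    if ar_order == 0:
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = rss / df
        cov = np.linalg.inv(X.T @ X)
        return GlmFit(
            beta=beta,
            sigma2=sigma2,
            rho=np.zeros(nv),
            df=df,
            design=design,
            spatial_shape=spatial_shape,
            _bin_index=np.zeros(nv, dtype=int),
            _bin_cov={0: cov},
        )

    denom = np.einsum("ij,ij->j", resid, resid)
    num = np.einsum("ij,ij->j", resid[1:], resid[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    rho = np.clip(rho, -0.98, 0.98)

    if voxel_size_mm is not None and ar_smooth_fwhm_mm > 0 and len(spatial_shape) == 3:
        rho = smooth_volumes(
            rho.reshape(spatial_shape), ar_smooth_fwhm_mm, voxel_size_mm
        ).reshape(-1)
        rho = np.clip(rho, -0.98, 0.98)

    bins = np.round(rho / rho_bin).astype(int)
    beta_w = np.empty_like(beta)
    sigma2 = np.empty(nv)
    bin_cov = {}
    for b in np.unique(bins):
        sel = bins == b
        r = b * rho_bin
        Xw = _whitening_matrix_apply(X, r)
        Yw = _whitening_matrix_apply(Y[:, sel], r)
        pinv_w = np.linalg.pinv(Xw)
        bb = pinv_w @ Yw
        rw = Yw - Xw @ bb
        beta_w[:, sel] = bb
        sigma2[sel] = np.einsum("ij,ij->j", rw, rw) / df
        bin_cov[int(b)] = np.linalg.inv(Xw.T @ Xw)

    return GlmFit(
        beta=beta_w,
        sigma2=sigma2,
        rho=rho,
        df=df,
        design=design,
        spatial_shape=spatial_shape,
        _bin_index=bins,
        _bin_cov=bin_cov,
    )


@dataclass
class ContrastMap:
    """Effect, standard-deviation and t maps for one contrast."""

    effect: np.ndarray
    sd: np.ndarray
    t: np.ndarray
    df: int
    name: str = ""

    @property
    def shape(self):
        return self.effect.shape


def compute_contrast(fit: GlmFit, task_weights, name: str = "") -> ContrastMap:
    """Contrast of task coefficients: effect = w'beta, t = effect / sd.

    ``task_weights`` spans the task columns only; drift and nuisance columns
    always get zero weight.
    """
    task_idx = fit.design.task_indices
    task_weights = np.asarray(task_weights, dtype=float)
    if task_weights.size != task_idx.size:
        raise ValueError(
            f"expected {task_idx.size} task weights, got {task_weights.size}"
        )
    if not np.any(task_weights):
        raise ValueError("contrast weights are all zero")
    w = np.zeros(fit.design.n_columns)
    w[task_idx] = task_weights

    effect = w @ fit.beta
    var = fit.sigma2 * fit.contrast_variance_scale(w)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, effect / np.where(sd > 0, sd, 1.0), np.nan)
    shape = fit.spatial_shape
    return ContrastMap(
        effect=effect.reshape(shape),
        sd=sd.reshape(shape),
        t=t.reshape(shape),
        df=fit.df,
        name=name,
    )


def combine_runs(maps: list[ContrastMap], name: str | None = None) -> ContrastMap:
    """Fixed-effects (inverse-variance) combination of contrast maps.

    effect = sum(e_i / s_i^2) / sum(1 / s_i^2); sd = sum(1/s_i^2)^(-1/2);
    degrees of freedom add.  Voxels with invalid sd in a run are excluded
    from that run's contribution; voxels with no valid run are NaN.
    """
    if not maps:
        raise ValueError("need at least one contrast map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("contrast maps are on different grids")
    wsum = np.zeros(shape)
    esum = np.zeros(shape)
    for m in maps:
        ok = np.isfinite(m.sd) & (m.sd > 0) & np.isfinite(m.effect)
        w = np.zeros(shape)
        w[ok] = 1.0 / m.sd[ok] ** 2
        wsum += w
        esum += w * np.where(ok, m.effect, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = np.where(wsum > 0, esum / np.maximum(wsum, 1e-300), np.nan)
        sd = np.where(wsum > 0, 1.0 / np.sqrt(np.maximum(wsum, 1e-300)), np.nan)
        t = effect / sd
    return ContrastMap(
        effect=effect,
        sd=sd,
        t=t,
        df=sum(m.df for m in maps),
        name=name if name is not None else maps[0].name,
    )


# ---------------------------------------------------------------------------
# standard contrast weight vectors


def sound_vs_silence_weights(task_names) -> np.ndarray:
    """Mean of all sound columns against the implicit silence baseline."""
    n = len(task_names)
    if n == 0:
        raise ValueError("no task columns")
    return np.full(n, 1.0 / n)


def category_contrast_weights(task_names, main_of: dict[str, str]) -> np.ndarray:
    """Macaque vocalizations minus non-vocal sounds.

    Works both for main-category designs (columns named after the two main
    categories) and subcategory designs (columns mapped through ``main_of``).
    """
    cats = [main_of.get(nm, nm) for nm in task_names]
    pos = [i for i, c in enumerate(cats) if c == "macaque_vocal"]
    neg = [i for i, c in enumerate(cats) if c == "non_vocal"]
    if not pos or not neg:
        raise ValueError("need columns of both main categories for this contrast")
    w = np.zeros(len(task_names))
    w[pos] = 1.0 / len(pos)
    w[neg] = -1.0 / len(neg)
    return w


def subcategory_weights(task_names, subcategory: str) -> np.ndarray:
    """Indicator contrast of a single subcategory versus silence."""
    if subcategory not in task_names:
        raise ValueError(f"{subcategory!r} not among task columns")
    w = np.zeros(len(task_names))
    w[list(task_names).index(subcategory)] = 1.0
    return w
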