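"""Covariates of no interest: eroded-compartment PCA and component-count search.

White-matter and CSF voxels carry physiological and scanner noise but no
task response, so principal components of their time series (after eroding
the masks to avoid gray-matter partial volume) make good nuisance
regressors.  The number of components kept per compartment is chosen, per
subject, to maximize the whole-brain peak t of the Sound-vs-Silence
contrast — the same data-driven rule the pipeline's reference analysis used
(with the circularity this implies documented; a fixed count is available
through configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import firstlevel, hemodynamics

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentPCs",
    "ComponentCountChoice",
    "RunGlmInput",
    "erode_mask",
    "compute_pcs",
    "select_component_counts",
]


def erode_mask(mask: np.ndarray, kernel_mm: float = 3.0, voxel_size_mm: float = 1.5) -> np.ndarray:
    """Morphological erosion with a cubic structuring element.

    The element spans ``kernel_mm`` center-to-center per axis (3x3x3 voxels
    for a 3 mm kernel on a 1.5 mm grid).  An empty result is legal but logs
    a warning (the structure was thinner than the element).
    """
    if kernel_mm <= 0:
        return mask.astype(bool).copy()
    half = int(round(kernel_mm / (2.0 * voxel_size_mm)))
    if half == 0:
        return mask.astype(bool).copy()
    structure = np.ones((2 * half + 1,) * 3, dtype=bool)
    out = ndimage.binary_erosion(mask.astype(bool), structure=structure)
    if mask.any() and not out.any():
        logger.warning(
            "erosion with %.1f mm cubic kernel emptied the mask "
            "(%d voxels in input)", kernel_mm, int(mask.sum())
        )
    return out


@dataclass
class CompartmentPCs:
    """Principal component time courses of one compartment's voxels."""

    compartment: str
    mask: np.ndarray
    components: np.ndarray  # (n_volumes, k), orthonormal columns
    explained_variance_ratio: np.ndarray


def compute_pcs(data: np.ndarray, mask: np.ndarray, k: int, compartment: str = "") -> CompartmentPCs:
    """Top-k principal component time courses of the masked voxels.

    Each voxel's time series is temporally centered (which also removes the
    grand mean); the left singular vectors of the (time x voxel) matrix are
    the component time courses, orthonormal and ordered by explained
    variance.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("compartment mask is empty")
    if k < 0:
        raise ValueError("k must be >= 0")
    X = data[mask].T.astype(float)  # (t, voxels)
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank of the masked data (max {rank})")
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    return CompartmentPCs(
        compartment=compartment,
        mask=mask,
        components=U[:, :k].copy(),
        explained_variance_ratio=evr[:k].copy(),
    )


class RunGlmInput(NamedTuple):
    """Everything needed to (re)fit one run during the count search."""

    data: np.ndarray  # percent-signal-change 4-D volume
    task_values: np.ndarray
    task_names: Sequence[str]
    timestamps: np.ndarray
    white_components: np.ndarray  # (n_volumes, k_max_white)
    csf_components: np.ndarray  # (n_volumes, k_max_csf)


@dataclass
class ComponentCountChoice:
    """Chosen (k_white, k_csf) and the full search table."""

    k_white: int
    k_csf: int
    objective: float
    table: pd.DataFrame


def _nuisance_block(run: RunGlmInput, kw: int, kc: int):
    cols, names = [], []
    if kw:
        cols.append(run.white_components[:, :kw])
        names += [f"wm_pc{j}" for j in range(kw)]
    if kc:
        cols.append(run.csf_components[:, :kc])
        names += [f"csf_pc{j}" for j in range(kc)]
    if not cols:
        return None, None
    return np.hstack(cols), names


def select_component_counts(
    runs: Sequence[RunGlmInput],
    brain_mask: np.ndarray,
    candidate_grid: Sequence[tuple[int, int]] | None = None,
    *,
    drift_order: int = 3,
    ar_order: int = 1,
) -> ComponentCountChoice:
    """Search the (k_white, k_csf) grid for the counts that maximize the
    subject-level whole-brain peak t of Sound vs. Silence.

    For every grid point the subject's runs are refit with that many
    components, the runs are pooled (inverse-variance), and the maximum t
    inside ``brain_mask`` is recorded.  Ties are broken toward the smallest
    k_white + k_csf, then the smallest k_white.
    """
    if not runs:
        raise ValueError("need at least one run")
    if candidate_grid is None:
        candidate_grid = list(product(range(9), range(9)))
    if not len(candidate_grid):
        raise ValueError("candidate grid is empty")

    rows = []
    failures = []
    for kw, kc in candidate_grid:
        try:
            maps = []
            for run in runs:
                nuis, nn = _nuisance_block(run, kw, kc)
                design = hemodynamics.assemble_design_matrix(
                    run.task_values,
                    run.task_names,
                    run.timestamps,
                    drift_order=drift_order,
                    nuisance=nuis,
                    nuisance_names=nn,
                )
                fit = firstlevel.fit_run_glm(run.data, design, ar_order=ar_order)
                w = firstlevel.sound_vs_silence_weights(run.task_names)
                maps.append(firstlevel.compute_contrast(fit, w, "sound_vs_silence"))
            combined = firstlevel.combine_runs(maps)
            obj = float(np.nanmax(combined.t[brain_mask]))
        except Exception as exc:  # noqa: BLE001 - record and keep searching
            failures.append((kw, kc, exc))
            continue
        rows.append({"k_white": int(kw), "k_csf": int(kc), "peak_t": obj})

    if not rows:
        raise RuntimeError(f"all component-count fits failed; first error: {failures[0][2]}")
    table = pd.DataFrame(rows)
    # argmax under the tie rule: highest peak t, then smallest total, then
    # smallest k_white
    order = table.sort_values(
        by=["peak_t", "k_white", "k_csf"],
        ascending=[False, True, True],
        key=None,
    )
    best_t = order.iloc[0]["peak_t"]
    ties = table[np.isclose(table["peak_t"], best_t, rtol=0, atol=0)]
    ties = ties.assign(total=ties["k_white"] + ties["k_csf"]).sort_values(
        by=["total", "k_white"]
    )
    best = ties.iloc[0]
    return ComponentCountChoice(
        k_white=int(best["k_white"]),
        k_csf=int(best["k_csf"]),
        objective=float(best["peak_t"]),
        table=table,
    )
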